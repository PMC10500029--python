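"""Differential marker expression between selected and non-selected cells.

The effect size is the two-sample Kolmogorov-Smirnov statistic (sup over x of
|F_a(x) - F_b(x)| of the empirical CDFs): 0 means the two distributions
coincide, 1 means disjoint supports.  Only the statistic is reported — it is
used as an effect size, not a test.  Scores are computed in the all-cells
scope and per cell type, and markers are rank-ordered by KS within scope.
Reported expression values are min-max normalized to [0, 1] per marker for
plotting; the KS statistic itself is invariant to any common strictly
monotone rescaling, so the normalization does not affect it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CellTable
from .selection import SelectionResult


def ks_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sample KS statistic in [0, 1]; both samples must be non-empty."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b).statistic)


def differential_markers(
    table: CellTable,
    selection: SelectionResult,
    min_cells: int = 10,
) -> pd.DataFrame:
    """KS score per marker, in the all-cells scope and per cell type.

    Only cells inside the selection scope are compared.  A scope (cell type)
    with fewer than ``min_cells`` selected or non-selected cells is flagged
    and its KS omitted.  Returns a tidy frame with columns ``scope``,
    ``marker``, ``ks``, ``rank``, ``direction`` (selected median higher/lower),
    ``n_selected``, ``n_nonselected``, ``flagged``.
    """
    sub = table.df.set_index("cell_id").loc[selection.cell_ids]
    sel = selection.selected
    scopes: list[tuple[str, np.ndarray]] = [("all", np.ones(len(sub), dtype=bool))]
    for t in sorted(sub["cell_type"].unique(), key=str):
        scopes.append((t, (sub["cell_type"] == t).to_numpy()))

    rows = []
    for scope_name, mask in scopes:
        s_mask = mask & sel
        n_mask = mask & ~sel
        ns, nn = int(s_mask.sum()), int(n_mask.sum())
        flagged = ns < min_cells or nn < min_cells
        for m in table.markers:
            vals = sub[m].to_numpy(dtype=float)
            lo, hi = vals.min(), vals.max()
            norm = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
            if flagged:
                ks, direction = np.nan, None
            else:
                a, b = norm[s_mask], norm[n_mask]
                ks = ks_statistic(a, b)
                med_s, med_n = float(np.median(a)), float(np.median(b))
                direction = (
                    None if med_s == med_n else ("higher" if med_s > med_n else "lower")
                )
            rows.append(
                {
                    "scope": scope_name,
                    "marker": m,
                    "ks": ks,
                    "direction": direction,
                    "n_selected": ns,
                    "n_nonselected": nn,
                    "flagged": flagged,
                }
            )
    out = pd.DataFrame(rows)
    out["rank"] = (
        out.groupby("scope")["ks"].rank(ascending=False, method="min")
    )
    return out.sort_values(["scope", "rank"]).reset_index(drop=True)
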