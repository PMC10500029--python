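"""Filter-response cell selection, per-sample frequency comparisons, and
neighborhood-size (k) choice.

A cell is *selected* for a filter when its bare filter response
(``w_f . x``) exceeds a threshold (default 0).  Per patient, the relative
frequency of selected cells among the member cells of that patient's
multi-cell inputs summarizes how strongly the learned signature occurs in
each condition; frequencies are compared across conditions with a two-sided
Wilcoxon rank-sum test (exact for small tie-free groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CellTable
from .model import TrainedModel
from .neighborhoods import BG_LABEL, MultiCellInput

#: significance level for step (1) of the local k-selection rule
LOCAL_ALPHA = 0.05


@dataclass
class SelectionResult:
    """Per-cell responses and selected flags for one filter.

    ``scope`` records which cells were scored: all cells appearing in any
    input (default) or every cell of the table.
    """

    cell_ids: np.ndarray
    response: np.ndarray
    selected: np.ndarray
    filter_index: int
    threshold: float
    scope: str

    def __post_init__(self) -> None:
        self._lut = pd.Series(self.selected, index=self.cell_ids)

    def selected_lookup(self, cell_ids: np.ndarray) -> np.ndarray:
        """Boolean selected flags for cell_ids; cells outside scope are False."""
        return self._lut.reindex(cell_ids, fill_value=False).to_numpy(dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "response": self.response, "selected": self.selected}
        )


def select_cells(
    model: TrainedModel,
    table: CellTable,
    inputs: Sequence[MultiCellInput],
    filter_index: int = 0,
    threshold: float = 0.0,
    scope: str = "inputs",
) -> SelectionResult:
    """Score every cell once by its filter response and flag response > threshold.

    ``scope='inputs'`` scores cells occurring in at least one input (the
    spec'd default); ``scope='all'`` scores every cell of the table, which the
    enrichment stage needs for the image-wide selected counts.
    """
    if scope == "inputs":
        if not inputs:
            raise ValueError("empty input list")
        ids = np.unique(np.concatenate([inp.member_cell_ids for inp in inputs]))
    elif scope == "all":
        ids = table.df["cell_id"].to_numpy()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    features = model.feature_names if model.feature_names is not None else table.markers
    sub = table.df.set_index("cell_id").loc[ids]
    X = sub[list(features)].to_numpy(dtype=float)
    if not 0 <= filter_index < model.n_filters:
        raise IndexError(f"filter index {filter_index} out of range")
    resp = X @ model.filter_weights[filter_index]
    return SelectionResult(
        cell_ids=np.asarray(ids),
        response=resp,
        selected=resp > threshold,
        filter_index=filter_index,
        threshold=threshold,
        scope=scope,
    )


def frequency_per_sample(
    selection: SelectionResult,
    inputs: Sequence[MultiCellInput],
    labels: Sequence | None = None,
) -> pd.DataFrame:
    """Relative frequency of selected member-cell occurrences per (sample, label).

    The denominator is the number of member-cell occurrences in that sample's
    inputs of that label class (a cell in several inputs counts each time).
    ``labels`` overrides the inputs' own labels (used to relabel functional-
    mode inputs into high/low groups).
    """
    if labels is not None and len(labels) != len(inputs):
        raise ValueError("labels must match inputs")
    rows: dict[tuple, list] = {}
    for i, inp in enumerate(inputs):
        lab = labels[i] if labels is not None else inp.label
        key = (inp.sample_id, lab)
        sel = selection.selected_lookup(inp.member_cell_ids)
        n, s = rows.get(key, (0, 0)) if key in rows else (0, 0)
        rows[key] = (n + len(sel), s + int(sel.sum()))
    out = pd.DataFrame(
        [
            {"sample_id": k[0], "label": k[1], "n_cells": v[0],
             "n_selected": v[1], "frequency": v[1] / v[0]}
            for k, v in rows.items()
            if v[0] > 0
        ]
    )
    return out.sort_values(["label", "sample_id"], key=lambda s: s.astype(str)).reset_index(drop=True)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration when both groups have <= 25 tie-free observations,
    normal approximation with tie and continuity corrections otherwise.  Two
    identical groups (all values tied) return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and max(len(a), len(b)) <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_frequencies(
    freqs: pd.DataFrame,
    group_a,
    group_b,
    samples: Sequence | None = None,
) -> dict:
    """Compare per-sample selected-cell frequencies between two label classes.

    Returns ``{'p': two-sided rank-sum p, 'direction': label with the larger
    median (None when undecidable), 'n_a', 'n_b'}``.  ``samples`` optionally
    restricts the comparison (e.g. to held-out samples).
    """
    f = freqs
    if samples is not None:
        f = f[f["sample_id"].isin(set(samples))]
    va = f.loc[f["label"] == group_a, "frequency"].to_numpy()
    vb = f.loc[f["label"] == group_b, "frequency"].to_numpy()
    if len(va) < 2 or len(vb) < 2:
        raise ValueError(
            f"need >=2 samples per group (got {len(va)} for {group_a!r}, {len(vb)} for {group_b!r})"
        )
    p = wilcoxon_rank_sum(va, vb)
    ma, mb = float(np.median(va)), float(np.median(vb))
    direction = None if ma == mb else (group_a if ma > mb else group_b)
    return {"p": p, "direction": direction, "n_a": len(va), "n_b": len(vb)}


def choose_k(per_k_results: dict, mode: str = "global", alpha: float = LOCAL_ALPHA):
    """Pick the neighborhood size from per-k validation comparisons.

    ``per_k_results`` maps k to a dict with ``condition_p`` (condition vs
    condition) and, for local mode, ``background_p`` (winning condition vs
    background).  Global mode: smallest ``condition_p`` wins.  Local mode:
    restrict to k with ``condition_p < alpha``, then take the smallest
    ``background_p``.  Ties break toward smaller k.  Local mode with no
    admissible k returns ``None``.
    """
    if not per_k_results:
        raise ValueError("no k evaluated")
    ks = sorted(per_k_results)
    if mode == "global":
        return min(ks, key=lambda k: (per_k_results[k]["condition_p"], k))
    if mode in ("local", "functional"):
        admissible = [k for k in ks if per_k_results[k]["condition_p"] < alpha]
        if not admissible:
            return None
        return min(admissible, key=lambda k: (per_k_results[k]["background_p"], k))
    raise ValueError(f"unknown mode {mode!r}")


def functional_groups(
    inputs: Sequence[MultiCellInput],
    high_label: str = "HIGH",
    low_label: str = "LOW",
) -> list[str]:
    """Relabel functional-mode inputs as high/low relative to the mean label
    across all considered neighborhoods."""
    vals = np.array([float(inp.label) for inp in inputs])
    if np.var(vals) == 0:
        raise ValueError("zero label variance: all functional labels identical")
    mean = vals.mean()
    return [high_label if v > mean else low_label for v in vals]
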