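"""Cell-type enrichment scores (ES) for selected cells in anchor neighborhoods.

Counts are taken per image.  With ``N`` cells in the image, ``N_T`` of type T,
``K`` cells in the (union of) anchor neighborhoods, ``K_T`` of them of type T,
and the superscript ``S`` marking selected cells, the *local* score is

    E_T   = K * N_T / N             (expected type-T cells in the neighborhood)
    E_T^S = K^S * N_T^S / N^S       (expected selected type-T cells there)
    S_T   = K_T / E_T
    S_T^S = K_T^S / E_T^S
    ES_T  = S_T^S / S_T

and the *global* score is

    E_T^S = N^S * N_T / N
    ES_T  = N_T^S / E_T^S

ES above one indicates enrichment of selected type-T cells.  Per cohort, a
cell type's ES is reported as the median across patients with the MAD
(median absolute deviation) as the error bar; a patient's value is the median
over that patient's images.  Zero denominators make the score undefined for
that (image, type); undefined entries are excluded from medians and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import logging

import numpy as np
import pandas as pd

from .io import CellTable
from .neighborhoods import BG_LABEL, MultiCellInput
from .selection import SelectionResult

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentCounts:
    """The eight per-image count aggregates used by the ES formulas."""

    image_id: object
    sample_id: object
    condition: object
    N: int
    K: int
    N_S: int
    K_S: int
    per_type: pd.DataFrame = field(repr=False)  # index: cell_type; cols N_T, K_T, N_T_S, K_T_S

    def validate(self) -> None:
        pt = self.per_type
        assert (pt >= 0).all().all()
        assert self.K <= self.N and self.N_S <= self.N and self.K_S <= self.K
        assert int(pt["N_T"].sum()) == self.N and int(pt["K_T"].sum()) == self.K
        assert int(pt["N_T_S"].sum()) == self.N_S and int(pt["K_T_S"].sum()) == self.K_S
        assert (pt["K_T_S"] <= np.minimum(pt["K_T"], pt["N_T_S"])).all()


def tabulate_counts(
    table: CellTable,
    selection: SelectionResult,
    inputs: Sequence[MultiCellInput],
    include_background: bool = False,
) -> list[EnrichmentCounts]:
    """Per-image counts; the neighborhood is the *union* of member cells of
    that image's anchor inputs (a cell shared by two anchors counts once).

    Background-labeled inputs are excluded from the neighborhood unless
    ``include_background`` — they control the classifier, not the niche.
    Cells outside the selection scope count as not selected.  Images with no
    inputs are skipped with a warning.
    """
    members: dict = {}
    for inp in inputs:
        if not include_background and inp.label == BG_LABEL:
            continue
        members.setdefault(inp.image_id, []).append(inp.member_cell_ids)

    out: list[EnrichmentCounts] = []
    for image_id in sorted(table.df["image_id"].unique(), key=str):
        sub = table.df[table.df["image_id"] == image_id]
        if image_id not in members:
            logger.warning("image %r has no anchor inputs; skipped", image_id)
            continue
        nbhd = np.unique(np.concatenate(members[image_id]))
        ids = sub["cell_id"].to_numpy()
        types = sub["cell_type"].to_numpy()
        sel = selection.selected_lookup(ids)
        in_nbhd = np.isin(ids, nbhd)
        per_type = (
            pd.DataFrame(
                {
                    "cell_type": types,
                    "N_T": 1,
                    "K_T": in_nbhd.astype(int),
                    "N_T_S": sel.astype(int),
                    "K_T_S": (in_nbhd & sel).astype(int),
                }
            )
            .groupby("cell_type")
            .sum()
        )
        ec = EnrichmentCounts(
            image_id=image_id,
            sample_id=sub["sample_id"].iloc[0],
            condition=sub["condition"].iloc[0],
            N=len(sub),
            K=int(in_nbhd.sum()),
            N_S=int(sel.sum()),
            K_S=int((in_nbhd & sel).sum()),
            per_type=per_type,
        )
        ec.validate()
        out.append(ec)
    return out


def _type_counts(counts: EnrichmentCounts, cell_type) -> tuple[int, int, int, int]:
    if cell_type in counts.per_type.index:
        r = counts.per_type.loc[cell_type]
        return int(r["N_T"]), int(r["K_T"]), int(r["N_T_S"]), int(r["K_T_S"])
    return 0, 0, 0, 0


def local_es(counts: EnrichmentCounts, cell_type) -> float | None:
    """Local ES_T = (K_T^S / E_T^S) / (K_T / E_T); ``None`` when undefined
    (a zero expectation or S_T = 0)."""
    N_T, K_T, N_T_S, K_T_S = _type_counts(counts, cell_type)
    if counts.N == 0 or counts.N_S == 0:
        return None
    E_T = counts.K * N_T / counts.N
    E_T_S = counts.K_S * N_T_S / counts.N_S
    if E_T <= 0 or E_T_S <= 0:
        return None
    S_T = K_T / E_T
    if S_T <= 0:
        return None
    return (K_T_S / E_T_S) / S_T


def global_es(counts: EnrichmentCounts, cell_type) -> float | None:
    """Global ES_T = N_T^S / (N^S * N_T / N); ``None`` when undefined."""
    N_T, _, N_T_S, _ = _type_counts(counts, cell_type)
    if counts.N == 0 or counts.N_S == 0 or N_T == 0:
        return None
    return N_T_S / (counts.N_S * N_T / counts.N)


def per_image_es(
    counts_list: Sequence[EnrichmentCounts],
    mode: str = "local",
    cell_types: Sequence | None = None,
) -> pd.DataFrame:
    """Tidy (sample, image, condition, cell_type, es) rows; undefined es = NaN."""
    fn = local_es if mode == "local" else global_es
    if cell_types is None:
        cell_types = sorted(
            {t for c in counts_list for t in c.per_type.index}, key=str
        )
    rows = []
    for c in counts_list:
        for t in cell_types:
            es = fn(c, t)
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "image_id": c.image_id,
                    "condition": c.condition,
                    "cell_type": t,
                    "es": np.nan if es is None else es,
                }
            )
    return pd.DataFrame(rows)


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def aggregate_es(per_image: pd.DataFrame, grouping: str = "condition") -> pd.DataFrame:
    """Cohort aggregation: per sample the median over its images (defined
    values only), then per (group, cell_type) the median and MAD over samples.

    Returns a tidy frame with ``median_es``, ``mad``, ``n_samples``,
    ``n_images_defined``, ``n_images_undefined``; groups with no defined value
    get ``median_es = NaN`` and are thereby flagged absent.
    """
    rows = []
    for (grp, t), sub in per_image.groupby([grouping, "cell_type"], sort=True):
        per_sample = []
        for _, ssub in sub.groupby("sample_id", sort=True):
            vals = ssub["es"].dropna().to_numpy()
            if len(vals):
                per_sample.append(float(np.median(vals)))
        defined = sub["es"].notna().sum()
        rows.append(
            {
                grouping: grp,
                "cell_type": t,
                "median_es": float(np.median(per_sample)) if per_sample else np.nan,
                "mad": _mad(np.array(per_sample)) if per_sample else np.nan,
                "n_samples": len(per_sample),
                "n_images_defined": int(defined),
                "n_images_undefined": int(len(sub) - defined),
            }
        )
    return pd.DataFrame(rows)


def enrichment_table(
    table: CellTable,
    selection: SelectionResult,
    inputs: Sequence[MultiCellInput],
    mode: str = "local",
) -> pd.DataFrame:
    """End-to-end convenience: counts -> per-image ES -> per-condition medians,
    plus each type's selected-to-total ratio (the bubble-size statistic) and a
    log-ES column for plotting."""
    counts = tabulate_counts(table, selection, inputs)
    pie = per_image_es(counts, mode=mode)
    agg = aggregate_es(pie, grouping="condition")

    ratios = []
    for cond, grp in agg.groupby("condition", sort=True):
        cl = [c.per_type for c in counts if c.condition == cond and len(c.per_type)]
        tot = pd.concat(cl).groupby(level=0).sum() if cl else pd.DataFrame()
        for t in grp["cell_type"]:
            if len(tot) and t in tot.index and tot.loc[t, "N_T"] > 0:
                ratios.append(float(tot.loc[t, "N_T_S"] / tot.loc[t, "N_T"]))
            else:
                ratios.append(np.nan)
    agg = agg.copy()
    agg["selected_ratio"] = ratios
    with np.errstate(divide="ignore"):
        agg["log_es"] = np.log(agg["median_es"])
    return agg
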