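"""Reproducible synthetic benchmark studies for the whole pipeline.

Two studies exercise the method end to end on generated cohorts:

* :func:`planted_recovery_study` — a cohort with a planted, spatially
  localized PD1 shift on niche-resident T cells in one condition; the local
  analysis should recover the planted subset (high validation accuracy, a
  significant held-out frequency difference in the affected condition,
  enrichment of the target type in the anchor niche, the shifted marker on
  top of the KS ranking, and high recall against the ground-truth mask).
* :func:`null_calibration_study` — replicate cohorts with zero effect; the
  pipeline's held-out condition-vs-condition frequency test must reject at
  its nominal level.

Study sizes are fixed, documented choices (see docs/methods.md); all
randomness is derived from explicit seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import enrichment_table
from .markers import differential_markers
from .pipeline import RunConfig, run_pipeline
from .simulate import PlantedEffect, SyntheticConfig, generate_cohort, ground_truth_mask


def planted_recovery_study(
    cohort_seed: int = 11,
    split_seed: int = 7,
    anchor_seed: int = 8,
    train_seed: int = 9,
    effect_size: float = 3.0,
    fraction_affected: float = 0.8,
    n_trials: int = 20,
    k: int = 20,
) -> dict:
    """Run the local-mode pipeline on a planted-effect cohort and measure
    recovery of the planted cell subset.

    The cohort: 12 samples per condition (6 held out per group), 6 images per
    sample, 1000 cells per image, with the generator's default niche structure
    and a ``+effect_size`` sd shift on PD1 for ``fraction_affected`` of the
    niche-resident target cells in the affected condition.
    """
    cfg = SyntheticConfig(
        samples_per_condition=12,
        images_per_sample=6,
        cells_per_image=1000,
        planted_effect=PlantedEffect(
            shifted_markers={"PD1": effect_size},
            fraction_affected=fraction_affected,
        ),
        seed=cohort_seed,
    )
    table = generate_cohort(cfg)
    mask = ground_truth_mask(cfg, table)
    run_config = RunConfig(
        mode="local",
        anchor_type=cfg.anchor_type,
        bg_anchor_mode="position",
        k_grid=[k],
        n_test_samples_per_condition=6,
        n_trials=n_trials,
        split_seed=split_seed,
        anchor_seed=anchor_seed,
        train_seed=train_seed,
    )
    result = run_pipeline(run_config, table=table, write_outputs=False, characterize=False)
    r = result.per_k[k]
    affected = cfg.planted_effect.affected_condition
    control = [c for c in cfg.conditions if c != affected][0]
    target = cfg.planted_effect.target_type

    cand = r["per_condition_filters"][affected]
    selection = cand["selection"]
    heldout = cand["heldout_comparison"]

    planted_ids = result.table.df.loc[mask, "cell_id"].to_numpy()
    lut = pd.Series(selection.selected, index=selection.cell_ids)
    recall = float(lut.reindex(planted_ids, fill_value=False).mean())

    es = enrichment_table(result.table, selection, r["inputs"], mode="local")
    def _es(cond):
        row = es[(es.cell_type == target) & (es.condition == cond)]
        return float(row["median_es"].iloc[0])

    shifts = differential_markers(result.table, selection)
    top = shifts[shifts.scope == "all"].iloc[0]

    return {
        "val_accuracy": float(result.model.val_score),
        "test_accuracy": float(r["report"].test_score),
        "heldout_p": float(heldout["p"]),
        "heldout_direction": heldout["direction"],
        "affected_condition": affected,
        "target_es_affected": _es(affected),
        "target_es_control": _es(control),
        "recall": recall,
        "top_marker": str(top.marker),
        "top_marker_ks": float(top.ks),
        "shifted_marker": list(cfg.planted_effect.shifted_markers)[0],
        "n_planted": int(mask.sum()),
        "n_cells": int(result.table.n_cells),
        "n_inputs": len(r["inputs"]),
    }


def null_calibration_study(
    n_replicates: int = 200,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I-error calibration of the held-out frequency test at zero effect.

    Each replicate: a fresh cohort of 6 samples per condition (2 images of 100
    cells each) with ``fraction_affected = 0`` (conditions exchangeable), a
    global-mode pipeline run (20 anchors per image, k = 10, 2 search trials)
    with 4 samples per condition held out, and the held-out rank-sum p-value.
    Returns the fraction of replicates with p <= alpha.
    """
    rng = np.random.default_rng(base_seed)
    rejections = 0
    pvals = []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2 ** 31 - 10))
        cfg = SyntheticConfig(
            samples_per_condition=6,
            images_per_sample=2,
            cells_per_image=100,
            planted_effect=PlantedEffect(fraction_affected=0.0),
            seed=rep_seed,
        )
        table = generate_cohort(cfg)
        run_config = RunConfig(
            mode="global",
            k_grid=[10],
            n_anchors_per_image=20,
            n_test_samples_per_condition=4,
            n_trials=2,
            split_seed=rep_seed + 1,
            anchor_seed=rep_seed + 2,
            train_seed=rep_seed + 3,
        )
        res = run_pipeline(run_config, table=table, write_outputs=False, characterize=False)
        p = res.heldout_comparison["p"]
        pvals.append(p)
        rejections += p <= alpha
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "alpha": alpha,
        "median_p": float(np.median(pvals)),
    }
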