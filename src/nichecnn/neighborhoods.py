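"""Construction of labeled multi-cell inputs from spatial k-nearest-neighbor
cell sets.

A *multi-cell input* is the unordered set of marker-expression vectors of the
``k`` cells nearest (Euclidean, within one image) to an anchor position,
carrying one label.  Three anchor regimes are supported:

* **global** — ``n`` anchors drawn uniformly per image; label = the image's
  condition.
* **local** — one anchor per cell of a chosen anchor cell type; label = the
  condition; plus a matched set of background ("BG") inputs around random
  anchors of any type, which forces the classifier to learn anchor-specific
  colocalization rather than image-wide composition.
* **functional** — anchors as in local mode, but the label is the mean of a
  chosen functional marker over the neighborhood, and that marker's column is
  removed from the feature matrix (``M - 1`` features).

Distance ties are broken by ascending ``cell_id`` so runs are bit-reproducible.
The anchor itself is excluded from its own neighborhood by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CellTable

logger = logging.getLogger(__name__)

#: label used for background inputs in local mode
BG_LABEL = "BG"


@dataclass
class MultiCellInput:
    """One anchor's neighborhood: a K x M' marker matrix plus provenance."""

    matrix: np.ndarray
    member_cell_ids: np.ndarray
    anchor_cell_id: object
    image_id: object
    sample_id: object
    label: object

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


@dataclass
class AnchorSpec:
    """Declarative description of how anchors are drawn."""

    mode: str  # 'global' | 'local' | 'functional'
    k: int
    anchor_cell_type: object | None = None
    n_anchors_per_image: int = 100
    functional_marker: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local", "functional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("local", "functional") and self.anchor_cell_type is None:
            raise ValueError(f"{self.mode} mode requires anchor_cell_type")
        if self.mode == "functional" and self.functional_marker is None:
            raise ValueError("functional mode requires functional_marker")


def _knn_indices(
    coords: np.ndarray, cell_ids: np.ndarray, anchor_pos: int, k: int,
    include_anchor: bool = False,
) -> np.ndarray:
    """Row indices of the k nearest cells to ``coords[anchor_pos]``.

    Exhaustive squared-distance evaluation with a (distance, cell_id) lexsort;
    images are small enough that this is both fast and exactly reproducible.
    """
    d2 = np.sum((coords - coords[anchor_pos]) ** 2, axis=1)
    order = np.lexsort((cell_ids, d2))
    if not include_anchor:
        order = order[order != anchor_pos]
    return order[:k]


def knn_query(image_cells: pd.DataFrame, anchor: object, k: int) -> list:
    """The ``k`` nearest cell_ids to the anchor cell within one image.

    ``image_cells`` must hold all cells of a single image with columns
    ``cell_id``, ``x``, ``y``.  The anchor is excluded from its own
    neighborhood; ties are broken by ascending ``cell_id``.
    """
    if len(image_cells) < k + 1:
        raise ValueError(f"image has {len(image_cells)} cells; need at least {k + 1}")
    ids = image_cells["cell_id"].to_numpy()
    pos = np.flatnonzero(ids == anchor)
    if pos.size != 1:
        raise ValueError(f"anchor cell {anchor!r} not found exactly once in image")
    coords = image_cells[["x", "y"]].to_numpy(dtype=float)
    idx = _knn_indices(coords, ids, int(pos[0]), k)
    return ids[idx].tolist()


def _iter_images(table: CellTable):
    """Yield (image_id, sample_id, condition, sub-DataFrame) deterministically."""
    df = table.df
    for image_id in sorted(df["image_id"].unique(), key=str):
        sub = df[df["image_id"] == image_id]
        yield image_id, sub["sample_id"].iloc[0], sub["condition"].iloc[0], sub


def _build_inputs_for_anchors(
    sub: pd.DataFrame,
    markers: Sequence[str],
    anchor_rows: np.ndarray,
    k: int,
    label,
    image_id,
    sample_id,
    include_anchor: bool,
    labels=None,
) -> list[MultiCellInput]:
    ids = sub["cell_id"].to_numpy()
    coords = sub[["x", "y"]].to_numpy(dtype=float)
    X = sub[list(markers)].to_numpy(dtype=float)
    out = []
    for j, a in enumerate(anchor_rows):
        idx = _knn_indices(coords, ids, int(a), k, include_anchor=include_anchor)
        out.append(
            MultiCellInput(
                matrix=X[idx].copy(),
                member_cell_ids=ids[idx].copy(),
                anchor_cell_id=ids[a],
                image_id=image_id,
                sample_id=sample_id,
                label=label if labels is None else labels[j],
            )
        )
    return out


def build_global_inputs(
    table: CellTable,
    k: int,
    n_anchors_per_image: int = 100,
    seed: int = 0,
    include_anchor: bool = False,
) -> list[MultiCellInput]:
    """Global mode: per image, draw anchors uniformly without replacement and
    take each anchor's k-NN as one input labeled with the image's condition.

    Images with fewer than ``k + 1`` cells are skipped with a warning; images
    with fewer cells than requested anchors contribute one input per cell.
    """
    rng = np.random.default_rng(seed)
    inputs: list[MultiCellInput] = []
    for image_id, sample_id, condition, sub in _iter_images(table):
        n = len(sub)
        if n < k + 1:
            logger.warning("image %r has %d cells < k+1=%d; skipped", image_id, n, k + 1)
            continue
        n_anchors = min(n_anchors_per_image, n)
        if n_anchors < n_anchors_per_image:
            logger.warning(
                "image %r has %d cells; sampling %d anchors instead of %d",
                image_id, n, n_anchors, n_anchors_per_image,
            )
        anchor_rows = rng.choice(n, size=n_anchors, replace=False)
        inputs.extend(
            _build_inputs_for_anchors(
                sub, table.markers, anchor_rows, k, condition,
                image_id, sample_id, include_anchor,
            )
        )
    return inputs


def build_local_inputs(
    table: CellTable,
    anchor_type,
    k: int,
    seed: int = 0,
    include_anchor: bool = False,
    bg_exclude_anchor_type: bool = False,
    bg_anchor_mode: str = "cell",
    n_background: int | None = None,
) -> list[MultiCellInput]:
    """Local mode: one input per anchor-type cell (label = condition) plus
    background inputs of randomly selected k-NN cell sets (label = ``"BG"``).

    The background count defaults to the mean per-condition input count so the
    label classes stay balanced; set ``n_background`` to override.  Background
    neighborhoods are anchored at random cells (``bg_anchor_mode='cell'``,
    optionally barring anchor-type cells via ``bg_exclude_anchor_type``) or at
    uniform random positions in each image's bounding box
    (``bg_anchor_mode='position'``), which samples generic tissue context
    rather than following the cell-density distribution.
    """
    if bg_anchor_mode not in ("cell", "position"):
        raise ValueError(f"unknown bg_anchor_mode {bg_anchor_mode!r}")
    if not (table.df["cell_type"] == anchor_type).any():
        raise ValueError(f"anchor type {anchor_type!r} absent from the table")
    rng = np.random.default_rng(seed)
    inputs: list[MultiCellInput] = []
    cond_counts: dict = {}
    eligible: list[tuple] = []  # (image_id, row position) usable for BG anchors

    per_image = {}
    for image_id, sample_id, condition, sub in _iter_images(table):
        if len(sub) < k + 1:
            logger.warning("image %r has %d cells < k+1=%d; skipped", image_id, len(sub), k + 1)
            continue
        per_image[image_id] = (sample_id, condition, sub)
        anchor_rows = np.flatnonzero((sub["cell_type"] == anchor_type).to_numpy())
        cond_counts[condition] = cond_counts.get(condition, 0) + len(anchor_rows)
        inputs.extend(
            _build_inputs_for_anchors(
                sub, table.markers, anchor_rows, k, condition,
                image_id, sample_id, include_anchor,
            )
        )
        if bg_exclude_anchor_type:
            rows = np.flatnonzero((sub["cell_type"] != anchor_type).to_numpy())
        else:
            rows = np.arange(len(sub))
        eligible.extend((image_id, r) for r in rows)

    if n_background is None:
        n_background = int(round(np.mean(list(cond_counts.values())))) if cond_counts else 0

    if bg_anchor_mode == "position" and per_image and n_background > 0:
        image_ids = sorted(per_image, key=str)
        assignment = rng.choice(len(image_ids), size=n_background, replace=True)
        for img_pos in range(len(image_ids)):
            n_here = int((assignment == img_pos).sum())
            if n_here == 0:
                continue
            image_id = image_ids[img_pos]
            sample_id, condition, sub = per_image[image_id]
            ids = sub["cell_id"].to_numpy()
            coords = sub[["x", "y"]].to_numpy(dtype=float)
            X = sub[list(table.markers)].to_numpy(dtype=float)
            lo, hi = coords.min(axis=0), coords.max(axis=0)
            pos = lo + rng.random((n_here, 2)) * (hi - lo)
            for p in pos:
                d2 = np.sum((coords - p) ** 2, axis=1)
                idx = np.lexsort((ids, d2))[:k]
                inputs.append(
                    MultiCellInput(
                        matrix=X[idx].copy(),
                        member_cell_ids=ids[idx].copy(),
                        anchor_cell_id=None,
                        image_id=image_id,
                        sample_id=sample_id,
                        label=BG_LABEL,
                    )
                )
        return inputs

    n_background = min(n_background, len(eligible))
    if n_background > 0:
        chosen = rng.choice(len(eligible), size=n_background, replace=False)
        by_image: dict = {}
        for c in chosen:
            image_id, r = eligible[c]
            by_image.setdefault(image_id, []).append(r)
        for image_id in sorted(by_image, key=str):
            sample_id, condition, sub = per_image[image_id]
            inputs.extend(
                _build_inputs_for_anchors(
                    sub, table.markers, np.array(sorted(by_image[image_id])), k,
                    BG_LABEL, image_id, sample_id, include_anchor,
                )
            )
    return inputs


def build_functional_inputs(
    table: CellTable,
    anchor_type,
    functional_marker: str,
    k: int,
    include_anchor: bool = False,
) -> list[MultiCellInput]:
    """Functional mode: anchors as in local mode; the label is the mean of the
    functional marker over the K neighborhood cells, and the feature matrix
    drops that marker's column (K x (M-1))."""
    if functional_marker not in table.markers:
        raise ValueError(f"functional marker {functional_marker!r} not in marker list")
    if table.n_markers < 2:
        raise ValueError("functional mode needs at least 2 markers (M-1 >= 1 features)")
    if not (table.df["cell_type"] == anchor_type).any():
        raise ValueError(f"anchor type {anchor_type!r} absent from the table")
    features = [m for m in table.markers if m != functional_marker]
    inputs: list[MultiCellInput] = []
    for image_id, sample_id, condition, sub in _iter_images(table):
        if len(sub) < k + 1:
            logger.warning("image %r has %d cells < k+1=%d; skipped", image_id, len(sub), k + 1)
            continue
        anchor_rows = np.flatnonzero((sub["cell_type"] == anchor_type).to_numpy())
        fvals = sub[functional_marker].to_numpy(dtype=float)
        ids = sub["cell_id"].to_numpy()
        coords = sub[["x", "y"]].to_numpy(dtype=float)
        X = sub[features].to_numpy(dtype=float)
        for a in anchor_rows:
            idx = _knn_indices(coords, ids, int(a), k, include_anchor=include_anchor)
            inputs.append(
                MultiCellInput(
                    matrix=X[idx].copy(),
                    member_cell_ids=ids[idx].copy(),
                    anchor_cell_id=ids[a],
                    image_id=image_id,
                    sample_id=sample_id,
                    label=float(fvals[idx].mean()),
                )
            )
    return inputs


# -- on-disk cache -------------------------------------------------------------

def save_inputs(inputs: Sequence[MultiCellInput], path) -> None:
    """Persist inputs to a compressed ``.npz`` so training can re-stream them
    without recomputing distances.  All inputs must share one K and M'."""
    if not inputs:
        raise ValueError("no inputs to save")
    X = np.stack([inp.matrix for inp in inputs])
    np.savez_compressed(
        path,
        matrices=X,
        member_cell_ids=np.stack([inp.member_cell_ids for inp in inputs]),
        anchor_cell_ids=np.array([inp.anchor_cell_id for inp in inputs]),
        image_ids=np.array([str(inp.image_id) for inp in inputs]),
        sample_ids=np.array([str(inp.sample_id) for inp in inputs]),
        labels=np.array([inp.label for inp in inputs]),
    )


def load_inputs(path) -> list[MultiCellInput]:
    z = np.load(path, allow_pickle=False)
    labels = z["labels"]
    return [
        MultiCellInput(
            matrix=z["matrices"][i],
            member_cell_ids=z["member_cell_ids"][i],
            anchor_cell_id=z["anchor_cell_ids"][i],
            image_id=z["image_ids"][i],
            sample_id=z["sample_ids"][i],
            label=labels[i].item() if labels.dtype.kind == "f" else str(labels[i]),
        )
        for i in range(len(labels))
    ]
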