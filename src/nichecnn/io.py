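"""Per-cell flat tables: loading, validation, preprocessing, and patient-level
train/validation/test assignment.

The central container is :class:`CellTable`, a thin wrapper around a pandas
DataFrame with one row per segmented cell.  Required roles are ``cell_id``,
``sample_id`` (patient/donor), ``image_id`` (nested under the sample),
planar coordinates ``x``/``y``, a categorical ``cell_type``, a sample-level
``condition``, plus an ordered list of marker-intensity columns.

Marker intensities are preprocessed the way the CODEX/IMC lineage does it:
``log(offset + x)`` followed by a Z-score per marker computed across the
whole dataset (not per image).
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, PreprocessError, SchemaError

#: canonical (role -> column) names used internally
ROLE_COLUMNS = ("cell_id", "sample_id", "image_id", "x", "y", "cell_type", "condition")

_PROVENANCE_PREFIX = "# nichecnn"


@dataclass
class CellTable:
    """A validated per-cell flat table.

    Parameters
    ----------
    df
        One row per cell with the canonical role columns plus one numeric
        column per marker.
    markers
        Marker column names in stable, declared order (length ``M``).
    preprocessed
        Whether marker columns hold log/Z-scored values instead of raw
        intensities.
    """

    df: pd.DataFrame
    markers: list[str]
    preprocessed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = list(self.markers)
        validate_cell_table(self.df, self.markers)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_matrix(self) -> np.ndarray:
        """N x M float array of marker values in declared marker order."""
        return self.df[self.markers].to_numpy(dtype=float)

    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def image_ids(self) -> list:
        return list(self.df["image_id"].unique())

    def sample_condition_map(self) -> dict:
        return dict(
            self.df.drop_duplicates("sample_id")[["sample_id", "condition"]].itertuples(
                index=False, name=None
            )
        )

    def copy(self) -> "CellTable":
        return CellTable(
            self.df.copy(), list(self.markers), self.preprocessed, dict(self.meta)
        )


def validate_cell_table(df: pd.DataFrame, markers: Sequence[str]) -> None:
    """Check the CellTable invariants, raising on the first violation."""
    missing = [c for c in ROLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    missing_m = [m for m in markers if m not in df.columns]
    if missing_m:
        raise SchemaError(f"missing marker columns: {missing_m}")
    if len(markers) == 0:
        raise SchemaError("at least one marker column is required")
    if df["cell_id"].duplicated().any():
        dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate cell_id (e.g. {dup!r})")
    if df[["x", "y"]].isna().any().any():
        raise IntegrityError("missing coordinates")
    for m in markers:
        if not np.issubdtype(df[m].dtype, np.number):
            raise SchemaError(f"marker column {m!r} is not numeric")
        if df[m].isna().any():
            raise IntegrityError(f"marker column {m!r} has missing values")
    img_samples = df.groupby("image_id", sort=False)["sample_id"].nunique()
    if (img_samples > 1).any():
        bad = img_samples[img_samples > 1].index[0]
        raise IntegrityError(f"image {bad!r} spans more than one sample")
    samp_cond = df.groupby("sample_id", sort=False)["condition"].nunique()
    if (samp_cond > 1).any():
        bad = samp_cond[samp_cond > 1].index[0]
        raise IntegrityError(f"sample {bad!r} maps to more than one condition")


def load_cell_table(path: str | Path, schema: dict) -> CellTable:
    """Read a delimited per-cell flat table.

    ``schema`` maps the canonical roles to column names in the file and must
    contain a ``markers`` entry listing marker columns in the order they
    should be kept.  Delimiter is chosen by extension (``.tsv`` -> tab,
    otherwise comma).  A provenance comment line written by
    :func:`write_cell_table` restores the ``preprocessed`` flag.
    """
    path = Path(path)
    if "markers" not in schema:
        raise SchemaError("schema must contain a 'markers' list")
    markers = list(schema["markers"])
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","

    preprocessed = False
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(_PROVENANCE_PREFIX):
            preprocessed = "preprocessed=true" in first
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body), sep=sep)

    rename = {}
    for role in ROLE_COLUMNS:
        col = schema.get(role, role)
        if col not in df.columns:
            raise SchemaError(f"column {col!r} for role {role!r} not found in {path}")
        rename[col] = role
    df = df.rename(columns=rename)
    for m in markers:
        if m not in df.columns:
            raise SchemaError(f"marker column {m!r} not found in {path}")
        if not np.issubdtype(df[m].dtype, np.number):
            raise SchemaError(f"marker column {m!r} failed to parse as numeric")
    keep = list(ROLE_COLUMNS) + markers
    return CellTable(df[keep].copy(), markers, preprocessed=preprocessed)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Serialize with a one-line provenance header comment."""
    path = Path(path)
    flag = "true" if table.preprocessed else "false"
    with open(path, "w") as fh:
        fh.write(f"{_PROVENANCE_PREFIX} preprocessed={flag}\n")
        table.df.to_csv(fh, index=False)


def preprocess_intensities(
    table: CellTable,
    offset: float = 1e-3,
    scaling_scope: str = "dataset",
    scope_samples: Sequence | None = None,
) -> CellTable:
    """Log-transform and Z-score marker intensities.

    Each marker value ``x`` becomes ``log(offset + x)`` (natural log), then
    every marker column is standardized to mean 0, sd 1.  Moments are taken
    across the whole dataset by default (``scaling_scope='dataset'``);
    ``scaling_scope='train_only'`` restricts moment estimation to
    ``scope_samples`` while still transforming every row.

    Raises
    ------
    PreprocessError
        If the table is already preprocessed, has negative raw intensities,
        or a marker column is constant (sd = 0).
    """
    if table.preprocessed:
        raise PreprocessError("table is already preprocessed")
    if scaling_scope not in ("dataset", "train_only"):
        raise ValueError(f"unknown scaling_scope {scaling_scope!r}")
    if scaling_scope == "train_only" and not scope_samples:
        raise ValueError("scaling_scope='train_only' requires scope_samples")

    df = table.df.copy()
    X = df[table.markers].to_numpy(dtype=float)
    if (X < 0).any():
        raise PreprocessError("raw intensities must be nonnegative")
    X = np.log(offset + X)

    if scaling_scope == "dataset":
        scope = np.ones(len(df), dtype=bool)
    else:
        scope = df["sample_id"].isin(set(scope_samples)).to_numpy()
        if not scope.any():
            raise ValueError("scope_samples matches no rows")
    mu = X[scope].mean(axis=0)
    sd = X[scope].std(axis=0)  # population sd (ddof=0)
    zero = np.flatnonzero((sd == 0) | (np.ptp(X[scope], axis=0) == 0))
    if zero.size:
        raise PreprocessError(
            f"constant marker column(s): {[table.markers[i] for i in zero]}"
        )
    df[table.markers] = (X - mu) / sd
    meta = dict(table.meta)
    meta["preprocess"] = {"offset": offset, "scaling_scope": scaling_scope}
    return CellTable(df, list(table.markers), preprocessed=True, meta=meta)


@dataclass
class SplitAssignment:
    """Patient-level test holdout plus the input-level train/val rule.

    ``test_samples`` are removed from training entirely (no patient leakage);
    the multi-cell inputs of the remaining samples are later partitioned into
    train/validation at ``1 - val_fraction`` / ``val_fraction``.
    """

    test_samples: frozenset
    val_fraction: float
    seed: int

    def partition_inputs(self, inputs: Sequence) -> dict[str, np.ndarray]:
        """Assign input indices to train/validation/test.

        Inputs whose ``sample_id`` is held out go to test; the rest are
        shuffled (seeded) and split at ``val_fraction``.
        """
        rng = np.random.default_rng(self.seed)
        idx_test, idx_rest = [], []
        for i, inp in enumerate(inputs):
            (idx_test if inp.sample_id in self.test_samples else idx_rest).append(i)
        idx_rest = np.array(idx_rest, dtype=int)
        rng.shuffle(idx_rest)
        n_val = int(round(self.val_fraction * len(idx_rest)))
        return {
            "validation": np.sort(idx_rest[:n_val]),
            "train": np.sort(idx_rest[n_val:]),
            "test": np.array(sorted(idx_test), dtype=int),
        }


def make_split(
    table: CellTable,
    n_test_samples_per_condition: int,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> SplitAssignment:
    """Draw held-out test samples per condition, without replacement.

    Reproducible under ``seed``.  Raises ``ValueError`` when a condition has
    no more samples than its test allotment (nothing would remain to train
    on).  ``n_test_samples_per_condition=0`` yields an empty test set.
    """
    if not 0 <= val_fraction < 1:
        raise ValueError("val_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    test: set = set()
    by_cond = table.df.drop_duplicates("sample_id").groupby("condition", sort=True)
    for cond, grp in by_cond:
        samples = sorted(grp["sample_id"].tolist())
        if n_test_samples_per_condition >= len(samples) and n_test_samples_per_condition > 0:
            raise ValueError(
                f"condition {cond!r} has {len(samples)} samples; cannot hold out "
                f"{n_test_samples_per_condition}"
            )
        if n_test_samples_per_condition > 0:
            chosen = rng.choice(samples, size=n_test_samples_per_condition, replace=False)
            test.update(chosen.tolist())
    return SplitAssignment(frozenset(test), val_fraction, seed)
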