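"""Samples x clustering-runs label matrices with explicit missingness.

The central input object is a rectangular grid of integer cluster labels:
rows are cohort samples, columns are independent clustering runs (e.g. one
run per multi-omics combination), and a cell is missing when the sample was
not covered by the data underlying that run.  Only *within-column* label
equality is meaningful — label alphabets are arbitrary per run and are never
canonicalized.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing label in the internal integer grid.
MISSING: int = -1

#: Marker written (and accepted, alongside the empty cell) in TSV files.
MISSING_MARKER: str = "NA"


class LabelMatrixError(ValueError):
    """Raised when a label matrix violates its structural invariants."""


@dataclasses.dataclass
class LabelMatrix:
    """Validated samples x runs grid of integer cluster labels.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers (rows).
    run_ids
        Ordered, unique clustering-run identifiers (columns).
    labels
        ``(n_samples, n_runs)`` int array; missing cells hold :data:`MISSING`,
        all other cells are positive integers.
    run_meta
        Optional per-run metadata indexed by run id with an integer
        ``n_omics`` column (number of omics platforms behind the run).
    """

    sample_ids: list[str]
    run_ids: list[str]
    labels: np.ndarray
    run_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.run_ids = [str(r) for r in self.run_ids]
        self._validate()

    # -- basic geometry ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_runs(self) -> int:
        return self.labels.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing cells, shape ``(n_samples, n_runs)``."""
        return self.labels != MISSING

    @property
    def coverage(self) -> np.ndarray:
        """Per-run fraction of observed samples, always recomputed."""
        return self.observed.mean(axis=0)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        if self.labels.ndim != 2:
            raise LabelMatrixError("labels must be a 2-D grid")
        n, r = self.labels.shape
        if len(self.sample_ids) != n or len(self.run_ids) != r:
            raise LabelMatrixError("id lists do not match the grid shape")
        if len(set(self.sample_ids)) != n:
            raise LabelMatrixError("duplicate sample ids")
        if len(set(self.run_ids)) != r:
            raise LabelMatrixError("duplicate run ids")
        obs = self.observed
        bad = obs & (self.labels < 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise LabelMatrixError(
                f"label at sample {self.sample_ids[i]!r}, run {self.run_ids[j]!r}"
                f" is not a positive integer: {self.labels[i, j]}"
            )
        # A column with < 2 observed samples carries no pairwise information.
        counts = obs.sum(axis=0)
        for j in np.nonzero(counts < 2)[0]:
            raise LabelMatrixError(
                f"run {self.run_ids[j]!r} has {counts[j]} non-missing entries;"
                " at least 2 are required"
            )
        if self.run_meta is not None:
            missing = [r_ for r_ in self.run_ids if r_ not in self.run_meta.index]
            if missing:
                raise LabelMatrixError(f"run_meta lacks entries for runs: {missing}")

    # -- convenience -------------------------------------------------------

    def subset_runs(self, keep: Sequence[int]) -> "LabelMatrix":
        """New matrix restricted to column positions ``keep`` (order kept)."""
        keep = list(keep)
        run_ids = [self.run_ids[j] for j in keep]
        meta = None
        if self.run_meta is not None:
            meta = self.run_meta.loc[run_ids]
        return LabelMatrix(self.sample_ids, run_ids, self.labels[:, keep], meta)

    def to_frame(self) -> pd.DataFrame:
        """Labels as a DataFrame with NA for missing cells."""
        df = pd.DataFrame(
            self.labels.astype(float), index=self.sample_ids, columns=self.run_ids
        )
        return df.mask(~self.observed)


@dataclasses.dataclass(frozen=True)
class StrategySpec:
    """Run-selection strategy over the number of omics platforms per run.

    ``EQUAL`` keeps runs built from exactly ``n`` platforms; ``LARGER`` keeps
    runs built from ``n`` or more.
    """

    mode: str
    n: int

    def __post_init__(self) -> None:
        if self.mode not in ("EQUAL", "LARGER"):
            raise ValueError(f"mode must be EQUAL or LARGER, got {self.mode!r}")
        if self.n < 1:
            raise ValueError("n must be a positive integer")

    def selects(self, n_omics: np.ndarray) -> np.ndarray:
        if self.mode == "EQUAL":
            return n_omics == self.n
        return n_omics >= self.n


# ---------------------------------------------------------------------------
# I/O


def read_label_matrix(
    path: str | Path,
    missing_marker: str = MISSING_MARKER,
    run_meta: pd.DataFrame | None = None,
) -> LabelMatrix:
    """Read a label matrix from TSV.

    Expected layout: header row of run ids, first column of sample ids,
    cells holding integers or the missing marker (an empty cell is also
    treated as missing).
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if df.index.has_duplicates:
        raise LabelMatrixError(f"duplicate sample ids in {path}")
    if df.columns.has_duplicates:
        raise LabelMatrixError(f"duplicate run ids in {path}")
    grid = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip() if isinstance(raw[i, j], str) else str(raw[i, j])
            if cell == missing_marker or cell == "":
                grid[i, j] = MISSING
            else:
                try:
                    grid[i, j] = int(cell)
                except ValueError:
                    raise LabelMatrixError(
                        f"non-integer cell {cell!r} at sample"
                        f" {df.index[i]!r}, run {df.columns[j]!r}"
                    ) from None
    return LabelMatrix(list(df.index), list(df.columns), grid, run_meta)


def write_label_matrix(m: LabelMatrix, path: str | Path) -> None:
    """Write the matrix as TSV; missing cells become :data:`MISSING_MARKER`."""
    out = np.where(m.observed, m.labels.astype(object), MISSING_MARKER)
    df = pd.DataFrame(out, index=m.sample_ids, columns=m.run_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_run_meta(path: str | Path) -> pd.DataFrame:
    """Read the sidecar run-metadata TSV (columns ``run_id``, ``n_omics``)."""
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str})
    if "run_id" not in df.columns or "n_omics" not in df.columns:
        raise LabelMatrixError("run metadata needs columns run_id and n_omics")
    df = df.set_index("run_id")
    df["n_omics"] = df["n_omics"].astype(int)
    if (df["n_omics"] < 1).any():
        raise LabelMatrixError("n_omics must be positive")
    return df


def write_run_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="run_id")


# ---------------------------------------------------------------------------
# Filtering


def filter_by_coverage(m: LabelMatrix, min_rate: float) -> LabelMatrix:
    """Keep runs whose recomputed sample coverage is >= ``min_rate``.

    The comparison is inclusive: a run covering exactly ``min_rate`` of the
    cohort is retained.  Column order is preserved.
    """
    if not (0 < min_rate <= 1):
        raise ValueError("min_rate must lie in (0, 1]")
    keep = np.nonzero(m.coverage >= min_rate)[0]
    if keep.size == 0:
        raise LabelMatrixError(
            f"no run reaches the coverage threshold {min_rate:g}"
        )
    return m.subset_runs(keep)


def select_runs(m: LabelMatrix, spec: StrategySpec) -> LabelMatrix:
    """Subset runs by their n-omics level under an EQUAL/LARGER strategy."""
    if m.run_meta is None:
        raise LabelMatrixError("select_runs requires run_meta with n_omics")
    n_omics = m.run_meta.loc[m.run_ids, "n_omics"].to_numpy()
    keep = np.nonzero(spec.selects(n_omics))[0]
    if keep.size == 0:
        raise LabelMatrixError(
            f"strategy {spec.mode} n={spec.n} selects no runs"
        )
    return m.subset_runs(keep)
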