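"""Containers and preprocessing for multi-subject region x time data.

A :class:`GroupDataset` holds k subjects' region-by-time matrices sharing a
common parcellation and acquisition grid.  Preprocessing utilities cover the
standard pipeline applied before any correlation analysis: discrete-cosine
high-pass filtering, nuisance regression, and within-subject z-scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupDataset",
    "RoiSet",
    "BehaviorSeries",
    "load_parcellated",
    "extract_roi_timeseries",
    "nuisance_regress",
    "highpass",
    "zscore_subjects",
    "zscore_rows",
]


@dataclass
class GroupDataset:
    """k subjects x p regions x n timepoints of region-averaged signals.

    Parameters
    ----------
    subjects : list of ndarray
        One ``(p, n)`` matrix per subject; all subjects must share the same
        region order and number of timepoints.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    region_labels : list of str, optional
        One label per region; defaults to ``r0..r{p-1}``.
    condition : str
        Free-form condition tag (e.g. ``"intact"``, ``"rest"``).
    degenerate : ndarray of bool, optional
        ``(k, p)`` flags marking zero-variance rows; set by
        :func:`zscore_subjects` and respected by all correlation code.
    """

    subjects: list[np.ndarray]
    tr_seconds: float = 1.5
    region_labels: list[str] = field(default_factory=list)
    condition: str = ""
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("no subjects: a GroupDataset needs at least one matrix")
        self.subjects = [np.asarray(x, dtype=float) for x in self.subjects]
        p, n = self.subjects[0].shape
        for i, x in enumerate(self.subjects):
            if x.ndim != 2:
                raise ValueError(f"subject {i}: expected a 2-D region x time matrix")
            if x.shape[0] != p:
                raise ValueError(
                    f"region mismatch: subject {i} has {x.shape[0]} regions, expected {p}"
                )
            if x.shape[1] != n:
                raise ValueError(
                    f"timepoint mismatch: subject {i} has {x.shape[1]} timepoints, expected {n}"
                )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.region_labels:
            self.region_labels = [f"r{i}" for i in range(p)]
        if len(self.region_labels) != p:
            raise ValueError("region_labels length must equal the region count")

    @property
    def k(self) -> int:
        return len(self.subjects)

    @property
    def p(self) -> int:
        return self.subjects[0].shape[0]

    @property
    def n(self) -> int:
        return self.subjects[0].shape[1]

    def stack(self) -> np.ndarray:
        """Return the data as a single ``(k, p, n)`` array."""
        return np.stack(self.subjects)

    def select_regions(self, idx: Sequence[int]) -> "GroupDataset":
        """Sub-dataset restricted to the given region indices (in order)."""
        idx = list(idx)
        return GroupDataset(
            [x[idx] for x in self.subjects],
            tr_seconds=self.tr_seconds,
            region_labels=[self.region_labels[i] for i in idx],
            condition=self.condition,
            degenerate=None if self.degenerate is None else self.degenerate[:, idx],
        )

    def window(self, start: int, length: int) -> "GroupDataset":
        """Sub-dataset over the half-open timepoint interval [start, start+length)."""
        if start < 0 or start + length > self.n:
            raise ValueError("window exceeds series bounds")
        return GroupDataset(
            [x[:, start : start + length] for x in self.subjects],
            tr_seconds=self.tr_seconds,
            region_labels=list(self.region_labels),
            condition=self.condition,
        )

    def to_dir(self, path: str | Path) -> None:
        """Write one TSV per subject (rows = timepoints, columns = regions)
        plus a JSON sidecar with tr/condition metadata."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, x in enumerate(self.subjects):
            pd.DataFrame(x.T, columns=self.region_labels).to_csv(
                path / f"sub-{i:03d}.tsv", sep="\t", index=False
            )
        meta = {"tr_seconds": self.tr_seconds, "condition": self.condition}
        (path / "dataset.json").write_text(json.dumps(meta, indent=1))


@dataclass
class RoiSet:
    """Named regions of interest over a voxel grid.

    ``rois`` maps each label to an integer array of shape ``(m, 3)`` of voxel
    indices (i, j, k).  An optional ``seed`` names a single sphere
    (label, center in mm, radius in mm) resolved against the volume affine.
    """

    rois: list[tuple[str, np.ndarray]]
    seed: tuple[str, tuple[float, float, float], float] | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, int]] = set()
        for label, vox in self.rois:
            vox = np.atleast_2d(np.asarray(vox, dtype=int))
            if vox.size == 0:
                raise ValueError(f"ROI '{label}' is empty")
            for v in map(tuple, vox):
                if v in seen:
                    raise ValueError(f"ROI '{label}' overlaps another ROI at voxel {v}")
                seen.add(v)


@dataclass
class BehaviorSeries:
    """Behavioral ratings attached to timepoints of the stimulus.

    scores: list of (timestamp_TR, value) with values on a 0-4 rating scale;
    span_TR: length of the underlying series in TRs.
    """

    scores: list[tuple[int, float]]
    span_TR: int

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.scores]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("behavior timestamps must be strictly increasing")
        for t, v in self.scores:
            if not (0.0 <= v <= 4.0):
                raise ValueError(f"rating {v} at TR {t} outside the 0-4 scale")
        if self.span_TR <= 0:
            raise ValueError("span_TR must be positive")

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([t for t, _ in self.scores], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.scores], dtype=float)


def load_parcellated(
    paths: str | Path | Iterable[str | Path], tr: float | None = None
) -> GroupDataset:
    """Load per-subject parcellated time series into a :class:`GroupDataset`.

    ``paths`` is either a directory containing ``sub-*.tsv`` files (one table
    per subject, rows = timepoints, header = region labels, sidecar
    ``dataset.json`` with ``tr_seconds``) or an explicit iterable of files.
    No z-scoring is applied.
    """
    condition = ""
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        root = Path(paths)
        files = sorted(root.glob("sub-*.tsv"))
        sidecar = root / "dataset.json"
        if tr is None and sidecar.exists():
            meta = json.loads(sidecar.read_text())
            tr = meta.get("tr_seconds")
            condition = meta.get("condition", "")
    else:
        files = [Path(p) for p in ([paths] if isinstance(paths, (str, Path)) else paths)]
    if not files:
        raise ValueError("no subjects: empty file list")
    if tr is None:
        raise ValueError("tr must be given or present in the dataset.json sidecar")

    subjects, labels = [], None
    for f in files:
        df = pd.read_csv(f, sep="\t")
        if labels is None:
            labels = list(df.columns)
        elif list(df.columns) != labels:
            raise ValueError(f"region mismatch: {f} has different region labels")
        subjects.append(df.to_numpy(dtype=float).T)
    try:
        return GroupDataset(subjects, tr_seconds=float(tr), region_labels=labels,
                            condition=condition)
    except ValueError as e:  # re-raise naming the offending file
        raise ValueError(f"{e} (while loading {[str(f) for f in files]})") from e


def extract_roi_timeseries(volume_4d, rois: RoiSet) -> np.ndarray:
    """Average a 4-D volume over each ROI's voxels, returning a (p, n) matrix.

    ``volume_4d`` is a nibabel spatial image (or anything with get_fdata()
    and affine).  A sphere seed, if present, is appended as the last row.
    """
    data = np.asarray(volume_4d.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D volume")
    rows = []
    for label, vox in rois.rois:
        vox = np.atleast_2d(np.asarray(vox, dtype=int))
        if (vox < 0).any() or (vox >= np.array(data.shape[:3])).any():
            raise ValueError(f"ROI '{label}' lies outside the volume grid")
        rows.append(data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0))
    if rois.seed is not None:
        label, center, radius = rois.seed
        ijk = np.indices(data.shape[:3]).reshape(3, -1).T
        aff = volume_4d.affine
        mm = ijk @ aff[:3, :3].T + aff[:3, 3]
        inside = np.linalg.norm(mm - np.asarray(center), axis=1) <= radius
        if not inside.any():
            raise ValueError(f"seed '{label}' contains no voxels within the volume")
        sel = ijk[inside]
        rows.append(data[sel[:, 0], sel[:, 1], sel[:, 2], :].mean(axis=0))
    return np.vstack(rows)


def nuisance_regress(X: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Project nuisance time courses out of each row of ``X``.

    Residuals of an ordinary least-squares fit of every row on the column
    space of [intercept, regressors].  Residual rows are orthogonal to each
    regressor and to the constant.
    """
    X = np.asarray(X, dtype=float)
    R = np.atleast_2d(np.asarray(regressors, dtype=float))
    if not np.isfinite(R).all():
        raise ValueError("regressors contain non-finite values")
    r, n = R.shape
    if r >= n:
        raise ValueError("need fewer regressors than timepoints")
    D = np.column_stack([np.ones(n), R.T])  # n x (r+1) design
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify which regressor columns fail to add rank
        bad = []
        for j in range(1, D.shape[1]):
            if np.linalg.matrix_rank(D[:, : j + 1]) == np.linalg.matrix_rank(D[:, :j]):
                bad.append(j - 1)
        raise ValueError(f"rank-deficient regressor set: collinear columns {bad}")
    beta, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    return X - (D @ beta).T


def _dct_drift_basis(n: int, tr: float, cutoff_period: float) -> np.ndarray:
    """Discrete-cosine drift basis: cosines with period >= cutoff_period.

    Component j (j >= 1) has frequency j / (2 n tr); all components up to the
    cutoff frequency 1/cutoff_period are included, as in standard DCT-based
    high-pass filtering of fMRI series.
    """
    n_comp = int(np.floor(2.0 * n * tr / cutoff_period))
    t = np.arange(n)
    basis = [np.ones(n) / np.sqrt(n)]
    for j in range(1, n_comp + 1):
        c = np.cos(np.pi * j * (t + 0.5) / n)
        basis.append(c / np.linalg.norm(c))
    return np.column_stack(basis)


def highpass(X: np.ndarray, cutoff_period: float, tr: float) -> np.ndarray:
    """Remove slow drift with period >= ``cutoff_period`` seconds.

    Implemented as regression on a discrete-cosine drift basis (DC plus all
    cosines below the cutoff frequency); the passband is untouched.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[-1]
    if cutoff_period <= 2.0 * tr:
        raise ValueError("cutoff period must exceed twice the sampling interval")
    B = _dct_drift_basis(n, tr, cutoff_period)  # n x m, orthonormal columns
    return X - (X @ B) @ B.T


def degenerate_rows(X: np.ndarray) -> np.ndarray:
    """Boolean mask of numerically-constant rows along the last axis."""
    mu = np.asarray(X, dtype=float).mean(axis=-1)
    sd = np.asarray(X, dtype=float).std(axis=-1, ddof=1)
    return sd <= 1e-12 * (np.abs(mu) + 1.0)


def zscore_rows(X: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row; returns (z, degenerate_mask).

    Zero-variance rows are left as zeros and flagged; the sample standard
    deviation (ddof=1) is the stored normalisation (correlations are
    invariant to this choice).
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, ddof=ddof, keepdims=True)
    # tolerance-based: a numerically-constant row (sd at rounding level) is
    # as meaningless for correlation as an exactly constant one
    degenerate = (sd <= 1e-12 * (np.abs(mu) + 1.0)).squeeze(-1)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / safe
    Z[degenerate] = 0.0
    return Z, degenerate


def zscore_subjects(ds: GroupDataset) -> GroupDataset:
    """Z-score every region time course within each subject.

    Degenerate (zero-variance) rows are flagged on the returned dataset and
    excluded from downstream correlation averaging rather than zero-filled
    into statistics.
    """
    zs, flags = [], []
    for x in ds.subjects:
        z, d = zscore_rows(x)
        zs.append(z)
        flags.append(d)
    return GroupDataset(
        zs,
        tr_seconds=ds.tr_seconds,
        region_labels=list(ds.region_labels),
        condition=ds.condition,
        degenerate=np.stack(flags),
    )
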