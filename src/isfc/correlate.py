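"""Inter-subject functional correlation (ISFC), ISC, and within-subject FC.

ISFC correlates one region's time course in one subject with every region's
time course in the *average of all other subjects*.  Because intrinsic
fluctuations and scanner/physiological noise are uncorrelated across
subjects, ISFC isolates the stimulus-locked component of inter-regional
covariance that ordinary within-subject functional connectivity (FC) mixes
with intrinsic structure.

The group matrix is built subject by subject (leave-one-out), Fisher
z-averaged across subjects, inverse-transformed, and symmetrised; its
diagonal is the inter-subject correlation (ISC) of each region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .datasets import GroupDataset, degenerate_rows, zscore_rows

__all__ = [
    "CorrMatrix",
    "fisher_average",
    "subject_isfc",
    "group_isfc",
    "isc",
    "seed_isfc",
    "group_fc",
]

_FISHER_CLIP = 1.0 - 1e-7


@dataclass
class CorrMatrix:
    """Symmetric p x p correlation matrix with ISFC/FC semantics.

    For ``kind="ISFC"`` the diagonal holds the inter-subject correlation of
    each region; for ``kind="FC"`` the diagonal is identically 1.
    """

    values: np.ndarray
    kind: str  # "ISFC" | "FC"
    k_subjects: int = 0
    fisher_averaged: bool = True
    region_labels: list[str] = field(default_factory=list)
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("CorrMatrix values must be square")
        if self.kind not in ("ISFC", "FC"):
            raise ValueError("kind must be 'ISFC' or 'FC'")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.abs(finite) > 1.0 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")
        if not self.region_labels:
            self.region_labels = [f"r{i}" for i in range(self.values.shape[0])]

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def diagonal_meaning(self) -> str:
        return "ISC" if self.kind == "ISFC" else "unity"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_labels,
                            columns=self.region_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def to_hdf5(self, path, name: str = "corr") -> None:
        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            d = f.create_dataset(name, data=self.values)
            d.attrs["kind"] = self.kind
            d.attrs["k_subjects"] = self.k_subjects
            d.attrs["fisher_averaged"] = self.fisher_averaged
            d.attrs["condition"] = self.condition
            d.attrs["region_labels"] = [str(s) for s in self.region_labels]

    @classmethod
    def from_hdf5(cls, path, name: str = "corr") -> "CorrMatrix":
        with h5py.File(path, "r") as f:
            d = f[name]
            return cls(
                d[()],
                kind=str(d.attrs["kind"]),
                k_subjects=int(d.attrs["k_subjects"]),
                fisher_averaged=bool(d.attrs["fisher_averaged"]),
                region_labels=[str(s) for s in d.attrs["region_labels"]],
                condition=str(d.attrs["condition"]),
            )


def fisher_average(r_values) -> float:
    """tanh(mean(atanh(r))) with clipping at |r| = 1 - 1e-7.

    NaN entries (degenerate correlations) are dropped before averaging.
    """
    r = np.asarray(r_values, dtype=float).ravel()
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("fisher_average of an empty (or all-invalid) list")
    return float(np.tanh(np.mean(np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP)))))


def _row_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B.

    Rows with zero variance yield NaN entries rather than raising.
    """
    Za, da = zscore_rows(A)
    Zb, db = zscore_rows(B)
    n = A.shape[-1]
    C = (Za @ Zb.T) / (n - 1)
    if da.any():
        C[da, :] = np.nan
    if db.any():
        C[:, db] = np.nan
    return C


def subject_isfc(X_i: np.ndarray, others_mean: np.ndarray) -> np.ndarray:
    """Subject-level ISFC: entry (a, b) = corr(X_i row a, others-average row b).

    Not generally symmetric.  Degenerate rows on either side propagate NaN.
    """
    X_i = np.asarray(X_i, dtype=float)
    others_mean = np.asarray(others_mean, dtype=float)
    if X_i.shape != others_mean.shape:
        raise ValueError("subject and others-average matrices must share a shape")
    return _row_corr(X_i, others_mean)


def _isfc_stack(X: np.ndarray) -> np.ndarray:
    """Group ISFC for a (k, p, n) (or batched (..., k, p, n)) stack.

    Returns the symmetrised Fisher-averaged matrix, shape (..., p, p).
    Assumes no degenerate rows (fast path used by surrogates and windows);
    :func:`group_isfc` handles degeneracy.
    """
    *lead, k, p, n = X.shape
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, ddof=1, keepdims=True)
    Z = (X - mu) / sd
    total = Z.sum(axis=-3, keepdims=True)
    zsum = np.zeros((*lead, p, p))
    for i in range(k):
        O = (total[..., 0, :, :] - Z[..., i, :, :]) / (k - 1)
        Omu = O.mean(axis=-1, keepdims=True)
        Osd = O.std(axis=-1, ddof=1, keepdims=True)
        Oz = (O - Omu) / Osd
        C = np.matmul(Z[..., i, :, :], np.swapaxes(Oz, -1, -2)) / (n - 1)
        zsum += np.arctanh(np.clip(C, -_FISHER_CLIP, _FISHER_CLIP))
    C = np.tanh(zsum / k)
    return 0.5 * (C + np.swapaxes(C, -1, -2))


def group_isfc(ds: GroupDataset) -> CorrMatrix:
    """Group ISFC matrix: leave-one-out subject matrices, Fisher-averaged,
    symmetrised.  The diagonal is the ISC of each region.

    Subjects whose rows are all degenerate are excluded (with a warning) and
    the subject count adjusted; individual degenerate rows propagate as NaN
    and are dropped from the Fisher average entrywise.
    """
    if ds.k < 2:
        raise ValueError("group ISFC needs at least 2 subjects")
    subjects = ds.subjects
    keep = [i for i, x in enumerate(subjects) if not degenerate_rows(x).all()]
    if len(keep) < len(subjects):
        import warnings

        dropped = sorted(set(range(len(subjects))) - set(keep))
        warnings.warn(f"excluding entirely degenerate subjects {dropped}")
        subjects = [subjects[i] for i in keep]
    k = len(subjects)
    if k < 2:
        raise ValueError("group ISFC needs at least 2 non-degenerate subjects")

    X = np.stack(subjects)
    degenerate = degenerate_rows(X)
    if not degenerate.any():
        C = _isfc_stack(X)
    else:
        # leave-one-out average is taken over z-scored signals so that every
        # subject contributes on a common scale; degenerate rows contribute 0
        Z = np.stack([zscore_rows(x)[0] for x in X])
        total = Z.sum(axis=0)
        zmats = []
        for i in range(k):
            others = (total - Z[i]) / (k - 1)
            Ci = subject_isfc(X[i], others)
            zmats.append(np.arctanh(np.clip(Ci, -_FISHER_CLIP, _FISHER_CLIP)))
        with np.errstate(invalid="ignore"):
            zbar = np.nanmean(np.stack(zmats), axis=0)
        C = np.tanh(zbar)
        C = 0.5 * (C + C.T)
    return CorrMatrix(C, kind="ISFC", k_subjects=k,
                      region_labels=list(ds.region_labels), condition=ds.condition)


def isc(ds: GroupDataset) -> np.ndarray:
    """Inter-subject correlation per region: the diagonal of the group ISFC."""
    return np.diag(group_isfc(ds).values).copy()


def seed_isfc(ds: GroupDataset, seed_index: int) -> np.ndarray:
    """Seed-based ISFC map: one row of the symmetrised group ISFC matrix."""
    if not (0 <= seed_index < ds.p):
        raise IndexError(f"seed index {seed_index} outside 0..{ds.p - 1}")
    return group_isfc(ds).values[seed_index].copy()


def _fc_stack(X: np.ndarray) -> np.ndarray:
    """Fisher-averaged within-subject correlation for a (..., k, p, n) stack."""
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, ddof=1, keepdims=True)
    Z = (X - mu) / sd
    n = X.shape[-1]
    C = np.matmul(Z, np.swapaxes(Z, -1, -2)) / (n - 1)
    zbar = np.arctanh(np.clip(C, -_FISHER_CLIP, _FISHER_CLIP)).mean(axis=-3)
    out = np.tanh(zbar)
    p = out.shape[-1]
    out[..., range(p), range(p)] = 1.0
    return out


def group_fc(ds: GroupDataset) -> CorrMatrix:
    """Within-subject FC, Fisher-averaged across subjects; diagonal forced to 1.

    Degenerate rows propagate NaN within a subject and are dropped from the
    entrywise Fisher average.
    """
    if ds.k < 1:
        raise ValueError("group FC needs at least 1 subject")
    X = ds.stack()
    degenerate = degenerate_rows(X)
    if not degenerate.any():
        C = _fc_stack(X)
    else:
        zmats = []
        for x in ds.subjects:
            Ci = _row_corr(x, x)
            zmats.append(np.arctanh(np.clip(Ci, -_FISHER_CLIP, _FISHER_CLIP)))
        with np.errstate(invalid="ignore"):
            C = np.tanh(np.nanmean(np.stack(zmats), axis=0))
        np.fill_diagonal(C, 1.0)
    return CorrMatrix(C, kind="FC", k_subjects=ds.k,
                      region_labels=list(ds.region_labels), condition=ds.condition)


def group_isfc_blocked(ds: GroupDataset, block: int = 256) -> CorrMatrix:
    """Block-wise group ISFC for large p; identical values to :func:`group_isfc`.

    Computes the p x p matrix in (block x block) tiles so that only
    O(block * n) standardised rows are resident per tile pair.
    """
    if ds.k < 2:
        raise ValueError("group ISFC needs at least 2 subjects")
    X = ds.stack()
    k, p, n = X.shape
    Z = np.empty_like(X)
    for i in range(k):
        Z[i], _ = zscore_rows(X[i])
    total = Z.sum(axis=0)
    zsum = np.zeros((p, p))
    for i in range(k):
        O = (total - Z[i]) / (k - 1)
        Oz, _ = zscore_rows(O)
        for a in range(0, p, block):
            za = Z[i][a : a + block]
            for b in range(0, p, block):
                C = (za @ Oz[b : b + block].T) / (n - 1)
                zsum[a : a + block, b : b + block] += np.arctanh(
                    np.clip(C, -_FISHER_CLIP, _FISHER_CLIP)
                )
    C = np.tanh(zsum / k)
    C = 0.5 * (C + C.T)
    return CorrMatrix(C, kind="ISFC", k_subjects=k,
                      region_labels=list(ds.region_labels), condition=ds.condition)
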