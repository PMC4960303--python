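"""Phase-randomization surrogates and max-statistic family-wise inference.

BOLD-like series carry long-range temporal autocorrelation, so naive
parametric p-values for correlations are invalid.  Significance is assessed
against surrogate data built by randomising the Fourier phases of each
series while preserving its amplitude spectrum (hence mean, variance and
autocorrelation).  Family-wise error over a whole correlation map is
controlled by recording the maximum statistic of each surrogate map and
thresholding the observed map at the upper (1-q) quantile of those maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .correlate import _fc_stack, _isfc_stack
from .datasets import GroupDataset

__all__ = [
    "NullDistribution",
    "SignificanceResult",
    "phase_randomize",
    "max_null",
    "fwer_threshold",
    "threshold_map",
    "perm_corr_pvalue",
]


@dataclass
class NullDistribution:
    """Sorted max-statistic samples from surrogate iterations."""

    samples: np.ndarray
    metric: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.sort(np.asarray(self.samples, dtype=float))

    @property
    def n_iter(self) -> int:
        return self.samples.size

    def threshold(self, q: float) -> float:
        return fwer_threshold(self, q)

    def to_hdf5(self, path, name: str = "null") -> None:
        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            d = f.create_dataset(name, data=self.samples)
            d.attrs["metric"] = self.metric
            d.attrs["seed"] = -1 if self.seed is None else int(self.seed)

    @classmethod
    def from_hdf5(cls, path, name: str = "null") -> "NullDistribution":
        with h5py.File(path, "r") as f:
            d = f[name]
            seed = int(d.attrs["seed"])
            return cls(d[()], metric=str(d.attrs["metric"]),
                       seed=None if seed < 0 else seed)


@dataclass
class SignificanceResult:
    """FWER-thresholded map: statistic > R* survives."""

    threshold: float
    q: float
    mask: np.ndarray
    values: np.ndarray

    @property
    def survivors(self) -> np.ndarray:
        return self.values[self.mask]


def _random_phase_factors(shape_lead: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-modulus factors for the rfft bins of a real length-n series.

    The DC bin (and the Nyquist bin for even n) must remain real, so their
    factors are fixed at 1; every other bin receives an independent
    Uniform(0, 2*pi) phase.  Conjugate symmetry of the full spectrum is
    implicit in the rfft representation.
    """
    n_bins = n // 2 + 1
    factors = np.ones((*shape_lead, n_bins), dtype=complex)
    lo, hi = 1, (n_bins - 1 if n % 2 == 0 else n_bins)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=(*shape_lead, hi - lo))
    factors[..., lo:hi] = np.exp(1j * phi)
    return factors


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomised surrogate(s) of the last axis of ``x``.

    The surrogate is real, has exactly the input's amplitude spectrum (so the
    same mean, variance and autocorrelation), and conjugate-symmetric phases.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples to phase-randomise")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    F = np.fft.rfft(x, axis=-1)
    factors = _random_phase_factors(x.shape[:-1], n, rng)
    return np.fft.irfft(F * factors, n=n, axis=-1)


def _map_max(C: np.ndarray, metric: str) -> np.ndarray:
    """Maximum over the unique elements of a symmetric map (batched).

    ISFC maps include the diagonal (ISC is part of the tested map); FC maps
    exclude it (the FC diagonal is identically 1).
    """
    p = C.shape[-1]
    iu = np.triu_indices(p, k=0 if metric == "isfc" else 1)
    return C[..., iu[0], iu[1]].max(axis=-1)


def max_null(
    ds: GroupDataset,
    statistic: str = "isfc",
    n_iter: int = 1000,
    rng: np.random.Generator | int | None = None,
    batch: int = 50,
) -> NullDistribution:
    """Null distribution of the map-wise maximum ISFC or FC value.

    Each iteration phase-randomises every region time course of every
    subject independently (breaking all dependence across regions and, for
    ISFC, across subjects), recomputes the full statistic map, and records
    its maximum.  Iterations are evaluated in vectorised batches; the drawn
    phases are identical to a sequential per-iteration loop.
    """
    if statistic not in ("isfc", "fc"):
        raise ValueError("statistic must be 'isfc' or 'fc'")
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = ds.stack()
    k, p, n = X.shape
    F = np.fft.rfft(X, axis=-1)  # spectrum computed once; phases vary per iter
    maxima = np.empty(n_iter)
    done = 0
    while done < n_iter:
        b = min(batch, n_iter - done)
        factors = _random_phase_factors((b, k, p), n, rng)
        surr = np.fft.irfft(F[None] * factors, n=n, axis=-1)
        C = _isfc_stack(surr) if statistic == "isfc" else _fc_stack(surr)
        maxima[done : done + b] = _map_max(C, statistic)
        done += b
    return NullDistribution(maxima, metric=statistic, seed=seed)


def fwer_threshold(null: NullDistribution, q: float) -> float:
    """R*: the (1-q)*100th percentile of the null maxima.

    Exceeding R* anywhere in the observed map has probability <= q under the
    null, giving family-wise error control at level q.  Linear interpolation
    between order statistics keeps the threshold continuous in q.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie strictly between 0 and 1")
    return float(np.quantile(null.samples, 1.0 - q))


def threshold_map(stat_map: np.ndarray, r_star: float, q: float = np.nan) -> SignificanceResult:
    """Boolean significance mask: statistic > R*."""
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.isfinite(stat_map).all():
        raise ValueError("statistic map contains non-finite values")
    return SignificanceResult(threshold=float(r_star), q=float(q),
                              mask=stat_map > r_star, values=stat_map)


def perm_corr_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Correlation with a phase-randomisation permutation p-value.

    r is the Pearson correlation of x and y; p is the two-sided fraction of
    surrogates of x whose |correlation with y| reaches |r|, with (b+1)/(m+1)
    smoothing so p is never exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D series of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (constant) series")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r = float(np.corrcoef(x, y)[0, 1])
    surr = phase_randomize(np.broadcast_to(x, (n_perm, x.size)).copy(), rng)
    zs = (surr - surr.mean(axis=1, keepdims=True)) / surr.std(axis=1, keepdims=True)
    zy = (y - y.mean()) / y.std()
    r_null = zs @ zy / x.size
    b = int(np.sum(np.abs(r_null) >= abs(r)))
    return r, (b + 1) / (n_perm + 1)
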