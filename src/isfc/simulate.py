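"""Synthetic multi-subject BOLD-like data under a three-component model.

Each measured region time course is a variance-budgeted mixture

    X_i = sqrt(s) * S  +  sqrt(1 - s - eta) * I_i  +  sqrt(eta) * N_i

of a stimulus-locked component S shared by every subject (drawn once with a
specified inter-regional correlation, optionally piecewise over interval
states), a per-subject intrinsic component I_i with its own inter-regional
correlation, and per-subject white noise N_i.  An optional per-subject
global confound — one scalar series added to all regions with
region-specific gain — emulates respiration/motion-like artefacts that
inflate within-subject FC but, being uncorrelated across subjects, leave
ISFC untouched.  Regions may integrate the stimulus over a leaky-integrator
timescale, making their shared signal history-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .datasets import BehaviorSeries, GroupDataset

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_group",
    "apply_memory",
    "scramble_segments",
    "simulate_behavior",
    "uniform_correlation",
]


def uniform_correlation(p: int, rho: float) -> np.ndarray:
    """p x p correlation matrix with every off-diagonal equal to rho."""
    if not (-1.0 / (p - 1) if p > 1 else -1.0) <= rho <= 1.0:
        raise ValueError("rho outside the positive-semidefinite range")
    C = np.full((p, p), float(rho))
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class SimConfig:
    """Generator configuration.

    Defaults reflect a typical narrative-listening acquisition: 18 subjects,
    10 network regions, ~7 minutes of data at TR 1.5 s, a stimulus that
    accounts for half the signal variance with moderate inter-regional
    correlation, an intrinsic network of comparable correlation, and 10% of
    variance as white measurement noise.
    """

    k: int = 18
    p: int = 10
    n: int = 280
    tr_seconds: float = 1.5
    stimulus_corr: np.ndarray | list[np.ndarray] | None = None  # C_S (per state)
    stimulus_share: float | np.ndarray = 0.5  # s, per region or scalar
    intrinsic_corr: np.ndarray | None = None  # C_I
    noise_share: float | np.ndarray = 0.1  # eta
    confound_sd: float = 0.0
    memory_tau_TR: float | np.ndarray = 0.0
    segments: list[tuple[int, int]] | None = None  # (start, length) tiles
    state_of_segment: list[int] | None = None  # index into stimulus_corr list
    seed: int | None = None
    condition: str = "sim"

    def __post_init__(self) -> None:
        if self.stimulus_corr is None:
            self.stimulus_corr = uniform_correlation(self.p, 0.6)
        if self.intrinsic_corr is None:
            self.intrinsic_corr = uniform_correlation(self.p, 0.3)
        s = np.broadcast_to(np.asarray(self.stimulus_share, float), (self.p,))
        eta = np.broadcast_to(np.asarray(self.noise_share, float), (self.p,))
        if (s < 0).any() or (s > 1).any():
            raise ValueError("stimulus_share must lie in [0, 1]")
        if (eta < 0).any() or (s + eta > 1 + 1e-12).any():
            raise ValueError("noise_share must be >= 0 with share + noise <= 1")

    @property
    def shares(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s = np.broadcast_to(np.asarray(self.stimulus_share, float), (self.p,)).copy()
        eta = np.broadcast_to(np.asarray(self.noise_share, float), (self.p,)).copy()
        return s, np.clip(1.0 - s - eta, 0.0, None), eta


@dataclass
class GroundTruth:
    """The generator's hidden components and bookkeeping."""

    S: np.ndarray  # p x n shared stimulus component (post-memory)
    I: list[np.ndarray] = field(default_factory=list)  # per-subject intrinsic
    N: list[np.ndarray] = field(default_factory=list)  # per-subject noise
    confounds: list[np.ndarray] = field(default_factory=list)  # per-subject 1 x n
    state_labels: np.ndarray | None = None  # per-timepoint interval state


def _chol_psd(C: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a PSD correlation matrix (eigen fallback)."""
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T):
        raise ValueError("covariance must be symmetric")
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        if w.min() < -1e-10:
            raise ValueError("covariance is not positive semi-definite") from None
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _draw_correlated(L: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return L @ rng.standard_normal((L.shape[1], n))


def apply_memory(S: np.ndarray, tau_TR: float | np.ndarray) -> np.ndarray:
    """Leaky integration of each row over timescale tau (in TRs).

    Rows with tau > 0 are replaced by y_t = lam * y_{t-1} + (1 - lam) * x_t
    with lam = exp(-1/tau), then re-standardised to unit variance; tau = 0
    rows pass through unchanged.  This realises history-dependent (context
    integrating) regions: the shared signal at time t depends on the
    stimulus over the preceding ~tau TRs.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    tau = np.broadcast_to(np.asarray(tau_TR, float), (p,))
    if (tau < 0).any():
        raise ValueError("tau must be non-negative")
    out = S.copy()
    for r in range(p):
        if tau[r] <= 0:
            continue
        lam = np.exp(-1.0 / tau[r])
        y = lfilter([1.0 - lam], [1.0, -lam], S[r])
        sd = y.std(ddof=1)
        out[r] = (y - y.mean()) / sd if sd > 0 else y
    return out


def _check_tiling(segments: list[tuple[int, int]], n: int) -> None:
    segs = sorted(segments)
    pos = 0
    for start, length in segs:
        if start != pos or length <= 0:
            raise ValueError("segments must tile the series without gaps or overlap")
        pos += length
    if pos != n:
        raise ValueError("segments must tile the full series")


def scramble_segments(
    S: np.ndarray,
    segments: list[tuple[int, int]],
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly permute the order of the given time segments of S.

    Returns the scrambled matrix and the permutation used (``perm[j]`` is the
    original index of the segment played j-th), so the inverse reordering can
    restore the original timeline.
    """
    S = np.asarray(S, dtype=float)
    _check_tiling(segments, S.shape[1])
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(len(segments))
    pieces = [S[:, s : s + l] for s, l in sorted(segments)]
    return np.concatenate([pieces[j] for j in perm], axis=1), perm


def simulate_group(
    cfg: SimConfig, stimulus: np.ndarray | None = None
) -> tuple[GroupDataset, GroundTruth]:
    """Draw one synthetic group under the three-component model.

    The stimulus component is drawn once (optionally piecewise: each segment
    takes the correlation matrix of its interval state), passed through the
    per-region memory integrator, and mixed into every subject with the
    configured variance budget.  Deterministic under ``cfg.seed``.

    ``stimulus`` supplies a pre-drawn (p, n) raw stimulus component instead
    of drawing one — used to present the *same* stimulus (or a scrambled
    version of it) to independent groups.
    """
    rng = np.random.default_rng(cfg.seed)
    p, n, k = cfg.p, cfg.n, cfg.k

    state_labels = None
    if stimulus is not None:
        S = np.asarray(stimulus, dtype=float)
        if S.shape != (p, n):
            raise ValueError("stimulus must have shape (p, n)")
    elif isinstance(cfg.stimulus_corr, (list, tuple)):
        if cfg.segments is None or cfg.state_of_segment is None:
            raise ValueError("piecewise stimulus_corr needs segments and state_of_segment")
        _check_tiling(cfg.segments, n)
        Ls = [_chol_psd(np.asarray(C)) for C in cfg.stimulus_corr]
        S = np.empty((p, n))
        state_labels = np.empty(n, dtype=int)
        for (start, length), st in zip(sorted(cfg.segments), cfg.state_of_segment):
            S[:, start : start + length] = _draw_correlated(Ls[st], length, rng)
            state_labels[start : start + length] = st
    else:
        S = _draw_correlated(_chol_psd(np.asarray(cfg.stimulus_corr)), n, rng)

    S = apply_memory(S, cfg.memory_tau_TR)

    s, intr, eta = cfg.shares
    L_I = _chol_psd(np.asarray(cfg.intrinsic_corr))
    gt = GroundTruth(S=S, state_labels=state_labels)
    subjects = []
    for _ in range(k):
        I_i = _draw_correlated(L_I, n, rng)
        N_i = rng.standard_normal((p, n))
        X = (
            np.sqrt(s)[:, None] * S
            + np.sqrt(intr)[:, None] * I_i
            + np.sqrt(eta)[:, None] * N_i
        )
        if cfg.confound_sd > 0:
            g = cfg.confound_sd * rng.standard_normal(n)
            gains = 0.5 + rng.uniform(0.0, 1.0, size=p)  # region-specific gain
            X = X + gains[:, None] * g[None, :]
            gt.confounds.append(g)
        gt.I.append(I_i)
        gt.N.append(N_i)
        subjects.append(X)

    ds = GroupDataset(subjects, tr_seconds=cfg.tr_seconds, condition=cfg.condition)
    return ds, gt


def expected_isfc_edge(s: float, rho_s: float, k: int) -> float:
    """Analytic expectation of a group-ISFC off-diagonal entry.

    For unit-variance signals, cov(X_i, others-mean) = s * rho_s while the
    leave-one-out average retains variance s + (1 - s)/(k - 1); hence

        E[r] ~= s * rho_s / sqrt(s + (1 - s) / (k - 1)).

    Derived here from the generative model; used as an independent oracle
    for the simulator, not as part of any estimator.
    """
    denom = np.sqrt(1.0 * (s + (1.0 - s) / (k - 1)))
    return float(s * rho_s / denom) if denom > 0 else 0.0


def simulate_behavior(
    mean_isfc_series: np.ndarray,
    coupling: float = 0.8,
    noise_sd: float = 0.5,
    n_blanks: int = 40,
    rng: np.random.Generator | int | None = None,
) -> BehaviorSeries:
    """Behavioral rating series coupled to a network-strength time course.

    Blank timestamps are placed uniformly over the series; each score is
    coupling * series(t) + noise, affinely mapped into the 0-4 rating scale.
    """
    if n_blanks < 3:
        raise ValueError("need at least 3 behavior points")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    series = np.asarray(mean_isfc_series, dtype=float)
    n = series.size
    ts = np.sort(rng.choice(n, size=min(n_blanks, n), replace=False))
    z = (series - series.mean()) / (series.std() if series.std() > 0 else 1.0)
    raw = coupling * z[ts] + noise_sd * rng.standard_normal(ts.size)
    lo, hi = raw.min(), raw.max()
    scaled = np.full_like(raw, 2.0) if hi == lo else 4.0 * (raw - lo) / (hi - lo)
    return BehaviorSeries(
        scores=[(int(t), float(v)) for t, v in zip(ts, scaled)], span_TR=n
    )
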