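"""Sliding-window network dynamics, fingerprints, reliability and coupling.

The network state in a time window is summarised either by the mean of the
lower off-diagonal correlations (a scalar "coupling strength") or by the
full vector of p(p-1)/2 edges (the window's "fingerprint").  Reliability of
those fingerprints is measured by split-half group comparison; behavioral
coupling correlates a smoothed rating series with the mean-coupling time
course under a phase-randomisation permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .correlate import CorrMatrix, group_fc, group_isfc
from .datasets import BehaviorSeries, GroupDataset
from .surrogates import perm_corr_pvalue

__all__ = [
    "WindowSeries",
    "Fingerprint",
    "NetworkGraphExport",
    "sliding_isfc",
    "sliding_fc",
    "mean_edges",
    "fingerprint",
    "fingerprint_to_matrix",
    "split_half_reliability",
    "reorder_segments",
    "behavior_coupling",
    "cross_network_isfc",
    "export_graph",
    "loess_smooth",
]


@dataclass
class WindowSeries:
    """Ordered sequence of window correlation matrices."""

    start_TRs: list[int]
    window_TR: int
    step_TR: int
    matrices: list[CorrMatrix]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.start_TRs, self.start_TRs[1:])):
            raise ValueError("window starts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.matrices)

    def mean_edge_series(self) -> np.ndarray:
        return np.array([mean_edges(C) for C in self.matrices])

    def fingerprints(self) -> np.ndarray:
        """(n_windows, n_edges) array of window fingerprints."""
        return np.stack([fingerprint(C).edges for C in self.matrices])


@dataclass
class Fingerprint:
    """Lower off-diagonal edges of a network correlation matrix.

    Edge order is fixed (lower triangle, row-major: (1,0), (2,0), (2,1), ...)
    so fingerprints are comparable across runs and serialisable with labels.
    """

    edges: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        m = self.edges.size
        p = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        if p * (p - 1) // 2 != m:
            raise ValueError("edge vector length is not p(p-1)/2 for any integer p")


@dataclass
class NetworkGraphExport:
    """Node/edge lists following the standard graph-display conventions:
    node diameter proportional to ISC, edge width = 60 x r for r >= 0, small
    negative edges (-0.1 < r < 0) width-zeroed, r <= -0.1 styled negative."""

    nodes: list[tuple[str, float, float]]  # (label, isc, diameter)
    edges: list[tuple[str, float, float]]  # (pair, r, width)

    def to_edge_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.edges, columns=["pair", "r", "width"]).to_csv(
            path, sep="\t", index=False
        )


def _tril_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(p, k=-1)


def mean_edges(C: CorrMatrix | np.ndarray) -> float:
    """Mean of the p(p-1)/2 lower off-diagonal entries (diagonal excluded)."""
    V = C.values if isinstance(C, CorrMatrix) else np.asarray(C, dtype=float)
    p = V.shape[0]
    if p < 2:
        raise ValueError("mean_edges needs at least 2 regions")
    i, j = _tril_indices(p)
    return float(V[i, j].mean())


def fingerprint(C: CorrMatrix | np.ndarray, labels: list[str] | None = None) -> Fingerprint:
    """Extract the fixed-order edge vector of a correlation matrix."""
    if isinstance(C, CorrMatrix):
        V, labels = C.values, C.region_labels
    else:
        V = np.asarray(C, dtype=float)
        labels = labels or [f"r{i}" for i in range(V.shape[0])]
    i, j = _tril_indices(V.shape[0])
    return Fingerprint(
        edges=V[i, j].copy(),
        labels=[f"{labels[a]}-{labels[b]}" for a, b in zip(i, j)],
    )


def fingerprint_to_matrix(fp: Fingerprint, diagonal: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric matrix from a fingerprint plus its diagonal."""
    p = diagonal.size
    V = np.zeros((p, p))
    i, j = _tril_indices(p)
    V[i, j] = fp.edges
    V = V + V.T
    V[np.arange(p), np.arange(p)] = diagonal
    return V


def _sliding(ds: GroupDataset, window_TR: int, step_TR: int, fn) -> WindowSeries:
    if window_TR > ds.n:
        raise ValueError("window longer than the series")
    if window_TR < 2 or step_TR < 1:
        raise ValueError("window must cover >= 2 TRs with step >= 1")
    starts = list(range(0, ds.n - window_TR + 1, step_TR))
    mats = [fn(ds.window(t, window_TR)) for t in starts]
    return WindowSeries(start_TRs=starts, window_TR=window_TR, step_TR=step_TR,
                        matrices=mats)


def sliding_isfc(ds: GroupDataset, window_TR: int, step_TR: int = 1) -> WindowSeries:
    """Group ISFC in half-open windows [t, t + window_TR), labeled by start TR."""
    return _sliding(ds, window_TR, step_TR, group_isfc)


def sliding_fc(ds: GroupDataset, window_TR: int, step_TR: int = 1) -> WindowSeries:
    """Within-subject FC in sliding windows, Fisher-averaged across subjects."""
    return _sliding(ds, window_TR, step_TR, group_fc)


def split_half_reliability(
    ds: GroupDataset,
    window_TR: int,
    step_TR: int = 1,
    n_iter: int = 100,
    rng: np.random.Generator | int | None = None,
    drop_odd: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Split-half reliability of window fingerprints.

    Each iteration randomly partitions the subjects into two equal groups,
    computes each group's sliding ISFC fingerprints, and correlates the two
    groups' fingerprints within each window.  Returns the per-window mean and
    standard deviation over iterations.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    k = ds.k
    if k % 2 == 1:
        if not drop_odd:
            raise ValueError("split-half needs an even subject count "
                             "(pass drop_odd=True to drop the last subject)")
        import warnings

        warnings.warn("odd subject count: dropping the last-listed subject")
        ds = GroupDataset(ds.subjects[:-1], tr_seconds=ds.tr_seconds,
                          region_labels=list(ds.region_labels), condition=ds.condition)
        k -= 1
    if k < 4:
        raise ValueError("split-half reliability needs at least 4 subjects")
    rs = []
    for _ in range(n_iter):
        perm = rng.permutation(k)
        half_a, half_b = perm[: k // 2], perm[k // 2 :]
        ws_a = sliding_isfc(_subset(ds, half_a), window_TR, step_TR)
        ws_b = sliding_isfc(_subset(ds, half_b), window_TR, step_TR)
        fa, fb = ws_a.fingerprints(), ws_b.fingerprints()
        za = (fa - fa.mean(axis=1, keepdims=True)) / fa.std(axis=1, keepdims=True)
        zb = (fb - fb.mean(axis=1, keepdims=True)) / fb.std(axis=1, keepdims=True)
        rs.append((za * zb).mean(axis=1))
    R = np.stack(rs)
    return R.mean(axis=0), R.std(axis=0, ddof=1 if n_iter > 1 else 0)


def _subset(ds: GroupDataset, idx) -> GroupDataset:
    return GroupDataset([ds.subjects[i] for i in idx], tr_seconds=ds.tr_seconds,
                        region_labels=list(ds.region_labels), condition=ds.condition)


def reorder_segments(
    ds: GroupDataset, segments: list[tuple[int, int]], order
) -> GroupDataset:
    """Re-concatenate every subject's time courses with segments in ``order``.

    ``segments`` must tile the series; ``order[j]`` gives the index (into the
    start-sorted segment list) of the segment to place j-th.  Passing
    ``np.argsort(perm)`` for the permutation returned by the simulator's
    segment scrambler restores the original timeline (for equal-length
    segments).
    """
    from .simulate import _check_tiling

    _check_tiling(segments, ds.n)
    order = np.asarray(order, dtype=int)
    segs = sorted(segments)
    if sorted(order.tolist()) != list(range(len(segs))):
        raise ValueError("order must be a permutation of the segment indices")
    cols = np.concatenate([np.arange(segs[j][0], segs[j][0] + segs[j][1]) for j in order])
    return GroupDataset([x[:, cols] for x in ds.subjects], tr_seconds=ds.tr_seconds,
                        region_labels=list(ds.region_labels), condition=ds.condition)


def loess_smooth(timestamps: np.ndarray, values: np.ndarray, span_TR: float,
                 xvals: np.ndarray) -> np.ndarray:
    """Local linear regression (tricube kernel) with span given in TRs,
    evaluated at ``xvals``."""
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    span = np.ptp(timestamps)
    # the local window must hold >= 4 points for a stable local linear fit
    frac = min(1.0, max(span_TR / span if span > 0 else 1.0, 4.0 / values.size))
    return lowess(values, timestamps, frac=frac, it=0, xvals=np.asarray(xvals, float))


def behavior_coupling(
    mean_isfc_series: np.ndarray,
    behavior: BehaviorSeries,
    window_starts: np.ndarray | None = None,
    span_TR: float = 30,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Correlate a smoothed behavior series with a mean-ISFC time course.

    Behavior scores are loess-smoothed over ``span_TR`` and resampled onto
    the window grid; significance comes from phase-randomisation surrogates
    of the ISFC series (two-sided, +1-smoothed).
    """
    series = np.asarray(mean_isfc_series, dtype=float)
    if len(behavior.scores) < 3:
        raise ValueError("need at least 3 behavior points")
    if behavior.values.std() == 0:
        raise ValueError("degenerate (constant) behavior series")
    if window_starts is None:
        window_starts = np.arange(series.size, dtype=float)
    ts = behavior.timestamps
    if ts.min() < 0 or ts.max() > behavior.span_TR:
        raise ValueError("behavior timestamps outside the series span")
    smooth = loess_smooth(ts, behavior.values, span_TR, np.asarray(window_starts, float))
    ok = np.isfinite(smooth)
    return perm_corr_pvalue(series[ok], smooth[ok], n_perm=n_perm, rng=rng)


def cross_network_isfc(
    ds: GroupDataset,
    membership: dict[str, str],
    window_TR: int,
    step_TR: int = 1,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-window mean ISFC between (and within) networks.

    ``membership`` maps each region label to a network name.  For a network
    pair (A, B) the series holds, per window, the mean over all matrix
    entries with one region in A and one in B; the within-network entry
    (A, A) is the mean of the sub-block's lower off-diagonal edges.
    """
    nets = sorted(set(membership.values()))
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    idx = {g: [i for i, lab in enumerate(ds.region_labels) if membership.get(lab) == g]
           for g in nets}
    for g, ii in idx.items():
        if not ii:
            raise ValueError(f"network '{g}' has no regions")
    ws = sliding_isfc(ds, window_TR, step_TR)
    out: dict[tuple[str, str], np.ndarray] = {}
    for a_i, a in enumerate(nets):
        for b in nets[a_i:]:
            vals = []
            for C in ws.matrices:
                V = C.values
                if a == b:
                    sub = V[np.ix_(idx[a], idx[a])]
                    vals.append(sub[0, 0] if len(idx[a]) == 1 else mean_edges(sub))
                else:
                    vals.append(float(V[np.ix_(idx[a], idx[b])].mean()))
            out[(a, b)] = np.array(vals)
    return out


def export_graph(C: CorrMatrix, isc_values: np.ndarray | None = None,
                 diameter_scale: float = 40.0) -> NetworkGraphExport:
    """Graph export: node size tracks ISC, edge width = 60 x r.

    Edges with -0.1 < r < 0 are exported with width 0; edges at r <= -0.1
    carry their (negative) width so renderers can style them separately.
    """
    V = C.values
    if isc_values is None:
        isc_values = np.diag(V) if C.kind == "ISFC" else np.ones(C.p)
    nodes = [(lab, float(v), float(diameter_scale * v))
             for lab, v in zip(C.region_labels, isc_values)]
    edges = []
    i, j = _tril_indices(C.p)
    for a, b in zip(i, j):
        r = float(V[a, b])
        if r >= 0:
            width = 60.0 * r
        elif r > -0.1:
            width = 0.0
        else:
            width = 60.0 * r
        edges.append((f"{C.region_labels[a]}-{C.region_labels[b]}", r, width))
    return NetworkGraphExport(nodes=nodes, edges=edges)
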