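"""Fingerprint decoding, k-means network discovery, and Dice reproducibility.

Decoding uses the simplest classifier consistent with correlation
fingerprints: leave-one-subject-out nearest template, where a test subject's
fingerprint (its subject-level ISFC against the remaining group, or its own
FC) is assigned to the class whose template — the Fisher-average of the
remaining subjects' fingerprints — it correlates with most strongly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .correlate import _FISHER_CLIP, subject_isfc
from .datasets import GroupDataset, zscore_rows
from .dynamics import _tril_indices

__all__ = [
    "ConfusionMatrix",
    "ClusterSolution",
    "chance_level",
    "subject_fingerprints",
    "classify_conditions",
    "classify_intervals",
    "kmeans_networks",
    "dice_matrix",
    "select_k",
    "decluster",
]


@dataclass
class ConfusionMatrix:
    """True x predicted counts for a classification task."""

    counts: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


@dataclass
class ClusterSolution:
    """A k-means partition of elements described by feature rows."""

    K: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int | None = None

    def members(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.labels == j)


def chance_level(n_classes: int) -> float:
    """Chance accuracy, in percent, for an n-way classification."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return 100.0 / n_classes


def _fisher_z(v: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(v, -_FISHER_CLIP, _FISHER_CLIP))


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation of each row of a with each row of b (rows standardized)."""
    za = (a - a.mean(axis=-1, keepdims=True)) / a.std(axis=-1, keepdims=True)
    zb = (b - b.mean(axis=-1, keepdims=True)) / b.std(axis=-1, keepdims=True)
    return za @ zb.T / a.shape[-1]


def subject_fingerprints(ds: GroupDataset, kind: str = "isfc") -> np.ndarray:
    """(k, p(p-1)/2) per-subject fingerprints.

    kind='isfc': each subject's leave-one-out ISFC matrix (vs the z-scored
    average of the other subjects), symmetrised; kind='fc': the subject's own
    correlation matrix.
    """
    X = ds.stack()
    k, p, n = X.shape
    Z = np.stack([zscore_rows(x)[0] for x in X])
    total = Z.sum(axis=0)
    i, j = _tril_indices(p)
    out = np.empty((k, i.size))
    for s in range(k):
        if kind == "isfc":
            C = subject_isfc(Z[s], (total - Z[s]) / (k - 1))
            C = 0.5 * (C + C.T)
        elif kind == "fc":
            C = subject_isfc(Z[s], Z[s])
        else:
            raise ValueError("kind must be 'isfc' or 'fc'")
        out[s] = C[i, j]
    return out


def _fold_features(ds: GroupDataset, test: int, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Leakage-free (test fingerprint, group template) pair for one fold.

    The test subject's feature is its subject-level matrix against the
    held-out group (its leave-one-out ISFC, or its own FC); the template is
    built from the remaining k-1 subjects alone — their mutual group ISFC,
    or their Fisher-averaged FC — so the test subject's data never enters
    the template.
    """
    from .correlate import group_fc, group_isfc

    k, p = ds.k, ds.p
    i, j = _tril_indices(p)
    others_idx = [s for s in range(k) if s != test]
    others = GroupDataset([ds.subjects[s] for s in others_idx],
                          tr_seconds=ds.tr_seconds,
                          region_labels=list(ds.region_labels))
    if kind == "isfc":
        Zt, _ = zscore_rows(ds.subjects[test])
        Zo = np.stack([zscore_rows(x)[0] for x in others.subjects])
        C = subject_isfc(Zt, Zo.mean(axis=0))
        C = 0.5 * (C + C.T)
        template = group_isfc(others).values
    elif kind == "fc":
        Zt, _ = zscore_rows(ds.subjects[test])
        C = subject_isfc(Zt, Zt)
        template = group_fc(others).values
    else:
        raise ValueError("kind must be 'isfc' or 'fc'")
    return C[i, j], template[i, j]


def _match(test_fp: np.ndarray, templates: np.ndarray, feature: str) -> int:
    """Nearest-template assignment on Fisher-z fingerprints.

    feature='full' matches by Pearson similarity of the whole fingerprint,
    feature='mean' by closest mean edge value; ties go to the lowest index.
    """
    t = _fisher_z(test_fp)[None]
    T = _fisher_z(templates)
    if feature == "full":
        sim = _corr_rows(t, T)[0]
    elif feature == "mean":
        sim = -np.abs(T.mean(axis=1) - t.mean())
    else:
        raise ValueError("feature must be 'full' or 'mean'")
    return int(np.argmax(sim))  # argmax ties -> lowest index


def classify_conditions(
    condition_datasets: dict[str, GroupDataset],
    kind: str = "isfc",
    feature: str = "full",
) -> tuple[float, ConfusionMatrix]:
    """Leave-one-subject-out decoding of the condition from fingerprints.

    ``condition_datasets`` maps each condition label to a
    :class:`GroupDataset` over the same k subjects.  For every held-out
    subject and condition, the subject's fingerprint is matched to the
    per-condition templates computed from the remaining subjects only.
    Returns (accuracy in percent, confusion matrix).
    """
    items = sorted(condition_datasets.items())
    labels = [lab for lab, _ in items]
    if len(labels) < 2:
        raise ValueError("need at least 2 conditions")
    k = items[0][1].k
    if k < 2:
        raise ValueError("need at least 2 subjects for leave-one-out decoding")
    if any(ds.k != k for _, ds in items):
        raise ValueError("all conditions must hold the same subjects")
    c = len(labels)
    counts = np.zeros((c, c), dtype=int)
    for test in range(k):
        folds = [_fold_features(ds, test, kind) for _, ds in items]
        templates = np.stack([tpl for _, tpl in folds])
        for true_c, (fp, _) in enumerate(folds):
            counts[true_c, _match(fp, templates, feature)] += 1
    cm = ConfusionMatrix(counts, labels)
    return 100.0 * cm.accuracy, cm


def classify_intervals(
    ds: GroupDataset,
    n_intervals: int = 14,
    interval_TR: int = 20,
    kind: str = "isfc",
    feature: str = "full",
) -> tuple[np.ndarray, float]:
    """Decode which story interval a fingerprint came from.

    For every held-out subject, per-interval templates are computed from the
    remaining k-1 subjects and the subject's interval fingerprint is
    assigned to the template it correlates with most strongly.  Returns
    per-subject accuracies and the group mean accuracy, both in percent
    (chance is 100/n_intervals).
    """
    if ds.n < n_intervals * interval_TR:
        raise ValueError("series too short for the requested intervals")
    windows = [ds.window(v * interval_TR, interval_TR) for v in range(n_intervals)]
    k = ds.k
    per_subject = np.empty(k)
    for test in range(k):
        folds = [_fold_features(w, test, kind) for w in windows]
        templates = np.stack([tpl for _, tpl in folds])
        hits = sum(_match(fp, templates, feature) == v
                   for v, (fp, _) in enumerate(folds))
        per_subject[test] = 100.0 * hits / n_intervals
    return per_subject, float(per_subject.mean())


def kmeans_networks(
    features: np.ndarray,
    K: int,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = None,
) -> ClusterSolution:
    """Best-of-restarts k-means (squared Euclidean objective, k-means++ seeding).

    ``features`` holds one row per element (e.g. the rows of a correlation
    matrix).  Deterministic under a fixed seed.
    """
    features = np.asarray(features, dtype=float)
    if K >= features.shape[0]:
        raise ValueError("K must be smaller than the number of elements")
    if K < 1:
        raise ValueError("K must be positive")
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(2**31 - 1))
    else:
        seed = rng
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed).fit(features)
    return ClusterSolution(K=K, labels=km.labels_.copy(),
                           centroids=km.cluster_centers_.copy(),
                           inertia=float(km.inertia_), seed=seed)


def dice_matrix(sol1: ClusterSolution, sol2: ClusterSolution) -> np.ndarray:
    """Sorensen-Dice overlap D(i, j) = 2|X_i & Y_j| / (|X_i| + |Y_j|)."""
    if sol1.labels.shape != sol2.labels.shape:
        raise ValueError("cluster solutions cover different element universes")
    D = np.zeros((sol1.K, sol2.K))
    for a in range(sol1.K):
        Xa = sol1.labels == a
        for b in range(sol2.K):
            Yb = sol2.labels == b
            denom = Xa.sum() + Yb.sum()
            D[a, b] = 2.0 * np.sum(Xa & Yb) / denom if denom else 0.0
    return D


def select_k(
    features_a: np.ndarray,
    features_b: np.ndarray,
    k_range,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose K by cross-group cluster reproducibility.

    For each candidate K the two group-halves' feature matrices are clustered
    independently; the score is the worst row of the Dice matrix after best
    matching (min over clusters of the row-max Dice).  The K with the highest
    score wins; ties go to the smaller K.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty candidate range")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    scores: dict[int, float] = {}
    for K in ks:
        sa = kmeans_networks(features_a, K, n_restarts, rng)
        sb = kmeans_networks(features_b, K, n_restarts, rng)
        D = dice_matrix(sa, sb)
        scores[K] = float(D.max(axis=1).min())
    best = max(sorted(scores), key=lambda K: (scores[K], -K))
    return best, scores


def decluster(
    series_map: dict,
    adjacency: dict,
    target_size: int,
) -> dict:
    """Grow contiguous ROIs by greedy neighborhood merging.

    Repeatedly merges the globally most-similar (Pearson) pair of adjacent
    clusters whose combined size stays within ``target_size``, replacing the
    pair's series with their average and recomputing similarities with the
    merged cluster's neighbors, until no admissible merge remains.  Ties
    break to the lowest-index pair (element order = insertion order).  An
    element with no neighbors stays a singleton (with a warning).  Returns a
    mapping element -> ROI id.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    elements = list(series_map)
    index = {e: i for i, e in enumerate(elements)}
    for e, nbrs in adjacency.items():
        for nb in nbrs:
            if e not in adjacency.get(nb, ()):  # symmetry check
                raise ValueError(f"adjacency not symmetric: {e} -> {nb}")
    isolated = [e for e in elements if not adjacency.get(e)]
    if isolated:
        import warnings

        warnings.warn(f"elements with no neighbors kept as singletons: {isolated}")

    cluster_of = {e: i for i, e in enumerate(elements)}
    members: dict[int, list] = {i: [e] for i, e in enumerate(elements)}
    series: dict[int, np.ndarray] = {
        i: np.asarray(series_map[e], dtype=float) for i, e in enumerate(elements)
    }
    neighbors: dict[int, set] = {
        i: {cluster_of[nb] for nb in adjacency.get(e, ())} for i, e in enumerate(elements)
    }

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0 or b.std() == 0:
            return -np.inf
        return float(np.corrcoef(a, b)[0, 1])

    while True:
        best, best_pair = -np.inf, None
        live = sorted(members)
        for a in live:
            for b in sorted(neighbors[a]):
                if b <= a:
                    continue
                if len(members[a]) + len(members[b]) > target_size:
                    continue
                r = corr(series[a], series[b])
                if r > best:  # strict: ties keep the earliest (lowest-index) pair
                    best, best_pair = r, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        members[a].extend(members[b])
        series[a] = 0.5 * (series[a] + series[b])
        neighbors[a] = (neighbors[a] | neighbors[b]) - {a, b}
        for c in neighbors[b]:
            if c != a:
                neighbors[c].discard(b)
                neighbors[c].add(a)
        neighbors[a].discard(a)
        del members[b], series[b], neighbors[b]

    out = {}
    for roi_id, (cid, elems) in enumerate(sorted(members.items())):
        for e in elems:
            out[e] = roi_id
    return out
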