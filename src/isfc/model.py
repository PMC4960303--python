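"""Model/Results front end over the ISFC and FC estimators.

`ISFCModel` (or `FCModel`) is constructed from a :class:`GroupDataset`;
``fit()`` estimates the group correlation matrix and, when surrogate
iterations are requested, the max-statistic null distribution and FWER
threshold.  The returned :class:`ConnectivityResults` carries the estimates,
their significance, and a ``summary()`` table; sliding-window estimation
hangs off the model as ``fit_windows()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .correlate import CorrMatrix, group_fc, group_isfc
from .datasets import GroupDataset, zscore_subjects
from .dynamics import WindowSeries, fingerprint, mean_edges, sliding_fc, sliding_isfc
from .surrogates import NullDistribution, fwer_threshold, max_null, threshold_map

__all__ = ["ISFCModel", "FCModel", "ConnectivityResults"]


class _ConnectivityModel:
    kind: str = ""

    def __init__(self, dataset: GroupDataset, zscore: bool = True):
        self.data = zscore_subjects(dataset) if zscore else dataset

    @classmethod
    def from_subject_frames(cls, frames, tr_seconds: float = 1.5, **kw):
        """Build from an iterable of (timepoints x regions) DataFrames."""
        frames = list(frames)
        labels = list(frames[0].columns)
        ds = GroupDataset([f.to_numpy(dtype=float).T for f in frames],
                          tr_seconds=tr_seconds, region_labels=labels)
        return cls(ds, **kw)

    def _estimate(self, ds: GroupDataset) -> CorrMatrix:
        return group_isfc(ds) if self.kind == "ISFC" else group_fc(ds)

    def fit(
        self,
        q: float = 0.01,
        n_surrogates: int = 0,
        seed: int | None = None,
    ) -> "ConnectivityResults":
        """Estimate the group matrix; with ``n_surrogates > 0`` also build the
        phase-randomisation null of map-wise maxima and the FWER threshold R*
        at level ``q``."""
        corr = self._estimate(self.data)
        null = r_star = None
        if n_surrogates:
            null = max_null(self.data, statistic=self.kind.lower(),
                            n_iter=n_surrogates, rng=seed)
            r_star = fwer_threshold(null, q)
        return ConnectivityResults(self, corr, null=null, q=q, threshold=r_star)

    def fit_windows(self, window_TR: int, step_TR: int = 1) -> WindowSeries:
        """Sliding-window estimation over half-open windows [t, t+window_TR)."""
        fn = sliding_isfc if self.kind == "ISFC" else sliding_fc
        return fn(self.data, window_TR, step_TR)


class ISFCModel(_ConnectivityModel):
    """Inter-subject functional correlation of a multi-subject dataset."""

    kind = "ISFC"


class FCModel(_ConnectivityModel):
    """Within-subject functional connectivity, Fisher-averaged over subjects."""

    kind = "FC"


class ConnectivityResults:
    """Fitted group connectivity with surrogate-based significance."""

    def __init__(
        self,
        model: _ConnectivityModel,
        corr: CorrMatrix,
        null: NullDistribution | None = None,
        q: float = 0.01,
        threshold: float | None = None,
    ):
        self.model = model
        self.corr = corr
        self.null = null
        self.q = q
        self.threshold = threshold

    @property
    def values(self) -> np.ndarray:
        return self.corr.values

    @property
    def isc(self) -> np.ndarray:
        """Region-wise inter-subject correlation (ISFC diagonal; ones for FC)."""
        return np.diag(self.corr.values).copy()

    @property
    def mean_edge(self) -> float:
        return mean_edges(self.corr)

    def significant(self):
        """FWER-thresholded map (requires a fitted null distribution)."""
        if self.threshold is None:
            raise ValueError("fit with n_surrogates > 0 to obtain a threshold")
        return threshold_map(self.corr.values, self.threshold, q=self.q)

    def edge_table(self) -> pd.DataFrame:
        fp = fingerprint(self.corr)
        df = pd.DataFrame({"edge": fp.labels, "r": fp.edges})
        if self.threshold is not None:
            df["significant"] = df["r"] > self.threshold
        return df

    def summary(self) -> str:
        c = self.corr
        lines = [
            f"{c.kind} results".ljust(40) + f"subjects: {c.k_subjects}",
            f"regions: {c.p}".ljust(40) + f"condition: {c.condition or '-'}",
            f"mean edge r: {self.mean_edge:+.4f}".ljust(40)
            + f"mean ISC: {np.mean(self.isc):.4f}",
        ]
        if self.threshold is not None:
            sig = self.significant()
            lines.append(
                f"R* (q={self.q:g}, {self.null.n_iter} surrogates): "
                f"{self.threshold:.4f}; suprathreshold elements: {int(sig.mask.sum())}"
            )
        head = max(len(s) for s in lines)
        bar = "=" * head
        body = "\n".join(lines)
        return f"{bar}\n{body}\n{bar}\n{self.edge_table().to_string(index=False)}"
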