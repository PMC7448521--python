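"""Greedy detection of disjoint signal regions within an associated gene.

The per-window significance threshold is the empirical lower-alpha quantile
of the Monte-Carlo null of the minimum window p-value, which controls at
level ~alpha the family-wise probability that any window passes under the
null.  Candidate windows below the threshold are then selected greedily:
take the smallest p-value, discard overlapping candidates, repeat.  The
overlap-fraction variant discards a candidate only when its overlap with a
selected region exceeds a fraction f (f = 1 keeps every passing window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .windows import Window

__all__ = [
    "SignalReport",
    "significance_threshold",
    "detect_signal_regions",
    "detect_signal_regions_overlap",
    "NONOVERLAP",
    "OVERLAP_FRACTION",
]

NONOVERLAP = "nonoverlap"
OVERLAP_FRACTION = "overlap_fraction"


@dataclass
class SignalReport:
    threshold: float
    alpha: float
    algorithm: str
    regions: list = field(default_factory=list)  # [(Window, p)] in selection order
    overlap_fraction: float | None = None

    def __post_init__(self):
        for k in range(1, len(self.regions)):
            if self.regions[k][1] < self.regions[k - 1][1]:
                raise ValueError("regions must be in ascending-p selection order")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def member_sets(self) -> list[frozenset]:
        return [w.members for w, _ in self.regions]

    def to_dataframe(self, variants=None):
        import pandas as pd

        rows = []
        for rank, (w, p) in enumerate(self.regions, start=1):
            ids = (
                ",".join(str(variants.variant_id[j]) for j in w.sorted_members())
                if variants is not None
                else ",".join(map(str, w.sorted_members()))
            )
            rows.append((rank, p, ids))
        return pd.DataFrame(rows, columns=["region_rank", "p", "members"])


def significance_threshold(null_min_p: np.ndarray, alpha: float) -> float:
    """Empirical lower-alpha quantile of the null minimum-p sample.

    Returns the order statistic at rank floor(alpha * B) (minimum rank 1);
    requires alpha * B >= 1, otherwise a larger Monte-Carlo sample is
    needed to resolve the quantile.
    """
    null_min_p = np.asarray(null_min_p, dtype=float).ravel()
    B = null_min_p.size
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    if B * alpha < 1.0:
        raise ValueError(
            f"B={B} Monte-Carlo replicates cannot resolve alpha={alpha}; increase B"
        )
    rank = max(1, int(np.floor(alpha * B)))
    return float(np.sort(null_min_p)[rank - 1])


def _candidate_order(candidates: list) -> list:
    # ties: smaller window first, then lexicographically smallest members
    return sorted(candidates, key=lambda wp: (wp[1], wp[0].size, wp[0].sorted_members()))


def detect_signal_regions(
    window_results: list, threshold: float, alpha: float = 0.05
) -> SignalReport:
    """Greedy non-overlapping selection among windows with p < threshold.

    ``window_results`` is a list of (Window, p) pairs for eligible windows.
    """
    candidates = _candidate_order(
        [(w, float(p)) for w, p in window_results if p < threshold]
    )
    regions = []
    while candidates:
        best = candidates.pop(0)
        regions.append(best)
        candidates = [c for c in candidates if not (c[0].members & best[0].members)]
    return SignalReport(threshold=threshold, alpha=alpha, algorithm=NONOVERLAP, regions=regions)


def detect_signal_regions_overlap(
    window_results: list, threshold: float, f: float, alpha: float = 0.05
) -> SignalReport:
    """Overlap-fraction variant: discard a candidate only when
    |A & B| / min(|A|, |B|) exceeds ``f`` for a selected region B."""
    if not (0.0 < f <= 1.0):
        raise ValueError("overlap fraction f must lie in (0, 1]")
    candidates = _candidate_order(
        [(w, float(p)) for w, p in window_results if p < threshold]
    )
    regions = []
    while candidates:
        best = candidates.pop(0)
        regions.append(best)
        kept = []
        for c in candidates:
            inter = len(c[0].members & best[0].members)
            frac = inter / min(c[0].size, best[0].size)
            if frac <= f:
                kept.append(c)
        candidates = kept
    return SignalReport(
        threshold=threshold,
        alpha=alpha,
        algorithm=OVERLAP_FRACTION,
        regions=regions,
        overlap_fraction=f,
    )
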