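"""HU density-mask classification of lung parenchyma.

Lung voxels are partitioned by Hounsfield-unit thresholds into emphysema,
normal lung, ground-glass opacity (GGO), semi consolidation and
consolidation; fibrosis is an overlapping report-only interval spanning the
upper semi-consolidation and lower consolidation range.  The integer HU
bounds of the clinical convention (emphysema < -950, normal -950..-701,
GGO -700..-501, semi consolidation -500..-201, consolidation -200..60,
fibrosis -500..0) are extended to continuous HU by half-open intervals at
half-integer cut points, so integer-valued volumes reproduce the integer
table exactly and no HU value falls in a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .grid import VolumeGrid


@dataclass(frozen=True)
class HUClass:
    name: str
    lo: float  # inclusive
    hi: float  # exclusive
    exclusive: bool = True  # member of the mutually exclusive partition


@dataclass
class HUClassScheme:
    """Ordered HU classification scheme; exclusive classes partition (-inf, hi_max)."""

    classes: list[HUClass] = field(default_factory=lambda: [
        HUClass("emphysema", -np.inf, -950.5),
        HUClass("normal", -950.5, -700.5),
        HUClass("ggo", -700.5, -500.5),
        HUClass("semi_consolidation", -500.5, -200.5),
        HUClass("consolidation", -200.5, 60.5),
        HUClass("fibrosis", -500.5, 0.5, exclusive=False),
    ])

    def __post_init__(self) -> None:
        exc = self.exclusive_classes
        for a, b in zip(exc, exc[1:]):
            if not a.hi <= b.lo:
                raise ValueError(f"exclusive classes {a.name} and {b.name} overlap")
            if a.hi != b.lo:
                raise ValueError(f"gap between {a.name} and {b.name}")

    @property
    def exclusive_classes(self) -> list[HUClass]:
        return [c for c in self.classes if c.exclusive]

    @property
    def overlap_classes(self) -> list[HUClass]:
        return [c for c in self.classes if not c.exclusive]

    @property
    def upper_bound(self) -> float:
        """HU above which a lung voxel is reported as unclassified."""
        return self.exclusive_classes[-1].hi


DEFAULT_SCHEME = HUClassScheme()


@dataclass
class ParenchymaReport:
    fractions: dict[str, float]          # per-class volume fraction
    unclassified_fraction: float         # HU above the scheme's upper bound
    total_voxels: int
    counts: dict[str, int]
    histogram_edges: np.ndarray          # 1-HU bin edges
    histogram_counts: np.ndarray         # voxel count per bin

    def check(self) -> None:
        """Assert the exact partition conservation law on integer counts."""
        total = Fraction(self.total_voxels)
        s = sum(Fraction(self.counts[c]) for c in self.counts
                if not c.startswith("_")) + Fraction(self._unclassified_count)
        assert s == total, "exclusive class counts + unclassified != total"

    _unclassified_count: int = 0


def _lung_hu(volume: VolumeGrid, exclude_airways: bool = True) -> np.ndarray:
    if volume.lung_mask is None or not volume.lung_mask.any():
        raise ValueError("lung mask is empty or missing")
    mask = volume.lung_mask
    if exclude_airways and volume.airway_mask is not None:
        mask = mask & ~volume.airway_mask
    vals = volume.hu[mask]
    n_nan = int(np.isnan(vals).sum())
    if n_nan:
        raise ValueError(f"{n_nan} NaN HU voxels inside the lung mask")
    return vals


def classify_parenchyma(volume: VolumeGrid, scheme: HUClassScheme | None = None,
                        exclude_airways: bool = True) -> ParenchymaReport:
    """Classify lung voxels into HU classes and report volume fractions.

    Every lung voxel lands in exactly one exclusive class or is counted
    unclassified (HU at or above the scheme's upper bound); overlap classes
    (fibrosis) are counted independently over their own interval.  Fractions
    use all lung-mask voxels as the denominator, so exclusive fractions plus
    the unclassified fraction sum to 1 exactly.
    """
    scheme = scheme or DEFAULT_SCHEME
    vals = _lung_hu(volume, exclude_airways=exclude_airways)
    n = vals.size
    counts: dict[str, int] = {}
    for c in scheme.classes:
        counts[c.name] = int(np.count_nonzero((vals >= c.lo) & (vals < c.hi)))
    n_unclassified = int(np.count_nonzero(vals >= scheme.upper_bound))

    fractions = {c.name: counts[c.name] / n for c in scheme.classes}
    edges, hist = _histogram(vals)
    report = ParenchymaReport(
        fractions=fractions,
        unclassified_fraction=n_unclassified / n,
        total_voxels=n,
        counts=counts,
        histogram_edges=edges,
        histogram_counts=hist,
    )
    report._unclassified_count = n_unclassified
    # partition conservation on integer counts
    assert sum(counts[c.name] for c in scheme.exclusive_classes) + n_unclassified == n
    return report


def _histogram(vals: np.ndarray, lo: int = -1024, hi: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Voxel counts per 1-HU bin over [lo, hi]; out-of-range voxels clipped in."""
    edges = np.arange(lo - 0.5, hi + 1.5, 1.0)
    clipped = np.clip(vals, lo, hi)
    hist, _ = np.histogram(clipped, bins=edges)
    return edges, hist.astype(np.int64)


def hu_histogram(volume: VolumeGrid, exclude_airways: bool = True,
                 lo: int = -1024, hi: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Voxels-per-HU histogram of the lung, as (bin_edges, counts).

    Counts sum to the lung voxel count; HU outside [lo, hi] are clipped into
    the boundary bins so nothing is dropped.
    """
    vals = _lung_hu(volume, exclude_airways=exclude_airways)
    return _histogram(vals, lo, hi)
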