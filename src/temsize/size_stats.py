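"""Per-specimen size-distribution summaries.

The regulatory quantity is the median of the number-based minimal Feret
diameter distribution of one TEM specimen (the pool of all retained
particles from its set of images).  For trueness assessment against
certified modal ECD values, the mode is estimated as the location of a
maximum-likelihood normal fit to the raw ECD values — fitting raw data
rather than a histogram makes the mode independent of binning; the
histogram (Freedman–Diaconis bins) is produced for display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class SizeDistribution:
    """Values (nm) of one specimen's retained particles plus provenance."""

    values: np.ndarray
    material: str | None = None
    day: int | None = None
    replicate: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def median_nm(self) -> float:
        return median_min_feret(self.values)


def median_min_feret(values) -> float:
    """Sample median; the mean of the two central order statistics for even n."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no particles survive the quantification filters")
    return float(np.median(values))


def modal_ecd(values) -> float:
    """Mode of a maximum-likelihood normal fit to the raw values.

    For a normal model the ML location equals the sample mean; on skewed
    samples this deliberately differs from the histogram peak (both are
    reported by :func:`histogram`).  Requires n >= 10 for a stable fit.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError(f"need at least 10 values for a stable fit, got {values.size}")
    loc, _scale = stats.norm.fit(values)
    return float(loc)


def histogram(values) -> tuple[np.ndarray, np.ndarray]:
    """Counts and bin edges with Freedman–Diaconis bin width (display only)."""
    values = np.asarray(values, dtype=float)
    return np.histogram(values, bins="fd")
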