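"""Box-and-whisker summaries (Tukey convention).

Shared percentile engine used for lateral-wind distributions, per-model
effective-swath-width summaries and mildew severity panels.  Hinges are the
25th/75th percentiles by linear interpolation between closest ranks; each
whisker extends to the furthest datum no further than 1.5 times the
inter-quartile range from its hinge; everything beyond is an outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UasswathError

__all__ = ["BoxStats", "summarize_box"]


@dataclass(frozen=True)
class BoxStats:
    median: float
    q25: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...] = field(default_factory=tuple)
    n: int = 0

    def __post_init__(self) -> None:
        if not (self.q25 <= self.median <= self.q75):
            raise UasswathError("box statistics must satisfy q25 <= median <= q75")


def summarize_box(values, interpolation: str = "linear") -> BoxStats:
    """Summarize ``values`` as a Tukey box plot.

    Parameters
    ----------
    values : array-like of float
        At least one finite value.
    interpolation : str
        Percentile method passed to :func:`numpy.percentile` (default
        ``"linear"``, i.e. linear interpolation between closest ranks).
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise UasswathError("cannot summarize an empty sample")
    q25, med, q75 = np.percentile(arr, [25, 50, 75], method=interpolation)
    iqr = q75 - q25
    lo_fence = q25 - 1.5 * iqr
    hi_fence = q75 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    # fences always bracket the hinges, so `inside` is never empty
    whisker_lo = float(inside.min())
    whisker_hi = float(inside.max())
    outliers = tuple(float(x) for x in arr[(arr < lo_fence) | (arr > hi_fence)])
    return BoxStats(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_lo=whisker_lo,
        whisker_hi=whisker_hi,
        outliers=outliers,
        n=int(arr.size),
    )
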