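"""Group-comparison statistics: paired t-test and percent difference.

The behavioral endpoint of the assay is a paired comparison of per-clip
swimming velocities between an exposed and a control group, with clips
paired by index. The test statistic is the classic one-sample t on the
within-pair differences, t = mean(d) / (sd(d)/sqrt(n)) with the sample
standard deviation (n-1 denominator), referred to Student's t with n-1
degrees of freedom, two-tailed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PairedTTestResult:
    n_pairs: int
    mean_diff: float
    sd_diff: float
    t_stat: float
    df: int
    p_two_tailed: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_two_tailed < alpha


class DegenerateVarianceWarning(UserWarning):
    """All within-pair differences identical and nonzero: sd(d) = 0."""


def paired_t_test(a, b) -> PairedTTestResult:
    """Two-tailed paired t-test of ``a`` versus ``b``, paired by index.

    Degenerate cases: if every difference is exactly zero, t = 0 and
    p = 1 (the samples are indistinguishable). If the differences are
    identical but nonzero the t statistic diverges; t = +/-inf and p = 0
    are reported with a :class:`DegenerateVarianceWarning`.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"samples must be equal-length 1-D, got {a.shape} and {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    df = n - 1
    if sd_diff == 0.0:
        if mean_diff == 0.0:
            return PairedTTestResult(n, 0.0, 0.0, 0.0, df, 1.0)
        warnings.warn(
            "all within-pair differences are identical and nonzero; "
            "t statistic is infinite",
            DegenerateVarianceWarning,
            stacklevel=2,
        )
        t_stat = math.copysign(math.inf, mean_diff)
        return PairedTTestResult(n, mean_diff, 0.0, t_stat, df, 0.0)
    t_stat = mean_diff / (sd_diff / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    return PairedTTestResult(n, mean_diff, sd_diff, float(t_stat), df, min(p, 1.0))


def percent_difference(mean_reference: float, mean_other: float) -> float:
    """Percent by which ``mean_other`` differs from ``mean_reference``.

    Returns ``100 * (mean_reference - mean_other) / mean_reference``:
    positive when the other group is below the reference (e.g. an
    exposed group swimming slower than control). Unrounded; round to
    one decimal for display.
    """
    if mean_reference == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (mean_reference - mean_other) / mean_reference
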