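"""Critical-point detection over the stage-ordered global-score series.

A stage t is flagged as the critical (pre-transition) point when

  (i)  PR(t) > PR(t-1), and
  (ii) PR(t) differs significantly from all prior values PR(1..t-1):
       the one-sample t statistic Z = (mean(X) - x) / (s / sqrt(n)),
       with X the n prior values, s their sample standard deviation
       (n - 1 denominator) and x = PR(t), has P < 0.05 against the
       Student t distribution with n - 1 degrees of freedom.

The first two score values can never be tested (the sample standard
deviation of a single prior is undefined), so eligibility starts at the
third value.  All flagged stages are reported; the summary's "critical
point" is the earliest.  Note that because x is a single draw rather
than a sample mean, this statistic is deliberately sensitive (it is not
calibrated as a textbook t-test under an i.i.d. null); the direction
gate (i) tempers but does not remove that.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("dnrs")

__all__ = ["one_sample_t", "detect_critical", "DetectionResult"]


def one_sample_t(
    prior: Sequence[float], x: float, one_sided: bool = False
) -> tuple[float, float]:
    """One-sample t statistic of x against the prior values.

    Returns (z, p) with z = (mean(prior) - x) / (sd(prior)/sqrt(n)) and p
    from Student t with n-1 degrees of freedom (two-sided by default; the
    one-sided variant tests whether x exceeds the prior mean).  When the
    prior values are all equal the convention is p = 1 if x equals their
    mean and p = 0 otherwise (z is +-inf accordingly).
    """
    prior = np.asarray(prior, dtype=float)
    n = len(prior)
    if n < 2:
        raise ValueError("need at least two prior values")
    mean = float(prior.mean())
    sd = float(prior.std(ddof=1))
    if sd == 0.0:
        if x == mean:
            return 0.0, 1.0
        return (math.inf if mean > x else -math.inf), 0.0
    z = (mean - x) / (sd / math.sqrt(n))
    if one_sided:
        # x above the prior mean drives z negative
        p = float(stats.t.cdf(z, df=n - 1))
    else:
        p = float(2.0 * stats.t.sf(abs(z), df=n - 1))
    return float(z), p


@dataclass
class DetectionResult:
    """Per-stage score series with test statistics and flagged stages."""

    stages: list[str]
    pr_series: np.ndarray
    z_series: np.ndarray          # NaN where not eligible
    p_series: np.ndarray          # NaN where not eligible
    eligible: np.ndarray          # bool mask
    flagged: list[str]
    first_critical: str | None
    p_threshold: float = 0.05
    one_sided: bool = False

    @property
    def flagged_indices(self) -> list[int]:
        return [self.stages.index(s) for s in self.flagged]

    @property
    def first_critical_index(self) -> int | None:
        return self.stages.index(self.first_critical) if self.first_critical else None

    def to_frame(self) -> pd.DataFrame:
        flagged = set(self.flagged)
        return pd.DataFrame(
            {
                "stage": self.stages,
                "pr": self.pr_series,
                "t_statistic": self.z_series,
                "p_value": self.p_series,
                "flagged": [int(s in flagged) for s in self.stages],
            }
        )


def detect_critical(
    pr_series: Sequence[float],
    stage_labels: Sequence[str] | None = None,
    p_threshold: float = 0.05,
    one_sided: bool = False,
) -> DetectionResult:
    """Scan the ordered score series for the critical point.

    Position t (0-based) is eligible once it has two or more prior values;
    it is flagged iff PR(t) > PR(t-1) and the one-sample t P-value of
    PR(t) against all priors is below ``p_threshold``.  A series shorter
    than 3 yields no eligible stage (warning, not an error).
    """
    pr = np.asarray(pr_series, dtype=float).ravel()
    m = len(pr)
    if stage_labels is None:
        stage_labels = [f"stage{i + 1}" for i in range(m)]
    stage_labels = [str(s) for s in stage_labels]
    if len(stage_labels) != m:
        raise ValueError("stage_labels length mismatch")
    if m < 3:
        warnings.warn(
            f"score series of length {m} has no eligible stages (need >= 3)",
            stacklevel=2,
        )
    z = np.full(m, np.nan)
    p = np.full(m, np.nan)
    eligible = np.zeros(m, dtype=bool)
    flagged: list[str] = []
    for t in range(2, m):
        eligible[t] = True
        z[t], p[t] = one_sample_t(pr[:t], pr[t], one_sided=one_sided)
        if pr[t] > pr[t - 1] and p[t] < p_threshold:
            flagged.append(stage_labels[t])
    return DetectionResult(
        stages=list(stage_labels),
        pr_series=pr,
        z_series=z,
        p_series=p,
        eligible=eligible,
        flagged=flagged,
        first_critical=flagged[0] if flagged else None,
        p_threshold=p_threshold,
        one_sided=one_sided,
    )
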