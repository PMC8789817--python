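"""Inference over split-half resamples with non-independence correction.

Scores computed on overlapping subject split-halves are not independent
samples, so naive paired t-tests are anti-conservative. The corrected
variance estimate inflates the per-difference variance by
``(1/J + n2/n1)`` where ``J`` is the number of resamples and ``n2/n1`` the
test/train size ratio of each resample (for subject split-halves,
``ceil(n/2)/floor(n/2)``). With ``correction_ratio = 0`` the test reduces
exactly to the classical paired t-test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTestError, InputError

_CLIP = 1.0 - 1e-7


def fisher_z(r) -> np.ndarray:
    """atanh with magnitude clipping so |r| = 1 stays finite."""
    r = np.clip(np.asarray(r, dtype=float), -_CLIP, _CLIP)
    return np.arctanh(r)


@dataclass
class CorrectedTestResult:
    t_statistic: float
    p_value: float
    n_splits: int
    correction_ratio: float
    mean_difference: float


def split_correction_ratio(n_subjects: int) -> float:
    """Test/train size ratio for subject split-halves: ceil(n/2)/floor(n/2)."""
    if n_subjects < 2:
        raise InputError("need at least 2 subjects")
    return np.ceil(n_subjects / 2) / np.floor(n_subjects / 2)


def corrected_paired_ttest(
    scores_a,
    scores_b,
    correction_ratio: float,
    fisher_transform: bool = False,
) -> CorrectedTestResult:
    """Paired t-test over resamples with corrected variance.

    ``fisher_transform=True`` maps both score lists through atanh before
    differencing (use when scores are correlations). Two-sided p-value from
    a t distribution with J-1 degrees of freedom.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("scores_a and scores_b must be 1-D and equally long")
    j = a.size
    if j < 2:
        raise DegenerateTestError("need at least 2 paired resamples")
    if correction_ratio < 0:
        raise InputError("correction_ratio must be nonnegative")
    if fisher_transform:
        a, b = fisher_z(a), fisher_z(b)
    d = a - b
    mean_d = float(d.mean())
    var_d = float(d.var(ddof=1))
    if var_d == 0.0:
        if mean_d == 0.0:
            # identical score lists: no evidence of a difference
            return CorrectedTestResult(0.0, 1.0, j, correction_ratio, 0.0)
        raise DegenerateTestError("zero variance with nonzero mean difference")
    t = mean_d / np.sqrt(var_d * (1.0 / j + correction_ratio))
    p = 2.0 * sps.t.sf(abs(t), df=j - 1)
    return CorrectedTestResult(float(t), float(p), j, correction_ratio, mean_d)


def adjusted_ci(rs, correction_ratio: float, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a mean correlation over non-independent splits.

    Computed on the Fisher-z scale as mean +/- t_{J-1} * sqrt(var * (1/J +
    correction_ratio)) and mapped back through tanh.
    """
    rs = np.asarray(rs, dtype=float)
    if rs.ndim != 1 or rs.size == 0:
        raise InputError("rs must be a nonempty 1-D sequence")
    j = rs.size
    if j < 2:
        raise DegenerateTestError("need at least 2 splits for a confidence interval")
    if not 0 < level < 1:
        raise InputError("level must be in (0, 1)")
    z = fisher_z(rs)
    mean_z = z.mean()
    var_z = z.var(ddof=1)
    tcrit = sps.t.ppf(0.5 * (1 + level), df=j - 1)
    half = tcrit * np.sqrt(var_z * (1.0 / j + correction_ratio))
    return float(np.tanh(mean_z - half)), float(np.tanh(mean_z + half))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected per-test alpha: alpha / m."""
    if m < 1:
        raise InputError("m must be >= 1")
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    return alpha / m
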