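"""Test-retest agreement: Bland-Altman limits and within-subject CoV.

Inputs are paired ROI means (scan 1, scan 2) from back-to-back acquisitions
without repositioning.  Limits of agreement use the plain 1.96 multiplier on
the sample SD of the differences (no small-sample t correction); the
within-subject coefficient of variation uses the root-mean-square
formulation for duplicate measurements,

    CoV = 100 * sqrt( sum_i d_i^2 / (2 n) ) / grand_mean,

whose square root of the half mean-squared difference is the within-subject
SD estimate for two replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RepeatabilityResult", "bland_altman", "within_subject_cov", "repeatability_analysis"]

LOA_MULTIPLIER = 1.96


@dataclass
class RepeatabilityResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    cov_within_percent: float
    n_subjects: int
    # Bland-Altman plot data: per-subject (mean of pair, difference)
    pair_means: np.ndarray | None = None
    pair_diffs: np.ndarray | None = None


def _as_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (scan1, scan2) means")
    return arr[:, 0], arr[:, 1]


def bland_altman(pairs) -> RepeatabilityResult:
    """Bias and 95% limits of agreement of scan2 - scan1 differences."""
    m1, m2 = _as_pairs(pairs)
    n = len(m1)
    if n < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 pairs")
    d = m2 - m1
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return RepeatabilityResult(
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        sd_diff=sd,
        cov_within_percent=within_subject_cov(pairs),
        n_subjects=n,
        pair_means=(m1 + m2) / 2.0,
        pair_diffs=d,
    )


def within_subject_cov(pairs) -> float:
    """Within-subject coefficient of variation for duplicate measurements, %."""
    m1, m2 = _as_pairs(pairs)
    if len(m1) < 1:
        raise ValueError("need at least one pair")
    grand_mean = float(np.concatenate([m1, m2]).mean())
    if grand_mean <= 0:
        raise ValueError("within-subject CoV requires a positive grand mean")
    d = m2 - m1
    ws_sd = np.sqrt((d**2).sum() / (2.0 * len(d)))
    return float(100.0 * ws_sd / grand_mean)


def repeatability_analysis(pairs) -> RepeatabilityResult:
    """Full repeatability summary (alias of :func:`bland_altman`)."""
    return bland_altman(pairs)
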