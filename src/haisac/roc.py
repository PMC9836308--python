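"""ROC analysis for screening-test discrimination.

Conventions follow screening practice for instruments where *lower* scores
mean more impairment: the impaired group supplies the cases, a subject is
called positive when the score is at or below the cutoff, and AUC is the
Mann-Whitney probability that a random case scores below a random control
(ties counted one half).  Optimal cutoffs maximize Youden's
J = sensitivity + specificity − 1 and are reported in the conventional
"a/b" form, the integer pair bracketing the midpoint between the last
positive and first negative achievable score.

AUC variances and paired AUC comparisons use DeLong's placement-value
(structural-components) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "DelongResult",
    "empirical_roc",
    "binormal_auc",
    "delong_paired_test",
    "auc_confidence_interval",
    "sens_spec_at_cutoff",
]


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with Youden-optimal operating point.

    ``thresholds`` are the pooled unique scores swept as candidate cutoffs;
    ``optimal_cutoff`` is the (a, b) integer pair bracketing the chosen
    boundary, with ``optimal_cutoff_label`` its "a/b" rendering.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    optimal_cutoff: tuple[int, int]
    optimal_sensitivity: float
    optimal_specificity: float
    youden_j: float
    ci_lower: float
    ci_upper: float
    auc_variance: float
    n_cases: int
    n_controls: int

    @property
    def optimal_cutoff_label(self) -> str:
        return f"{self.optimal_cutoff[0]}/{self.optimal_cutoff[1]}"


@dataclass(frozen=True)
class DelongResult:
    """DeLong comparison of two AUCs measured on the same subjects."""

    auc_1: float
    auc_2: float
    variance_diff: float
    statistic: float  # chi-square on 1 df (z squared)
    z: float
    p_value: float


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components under the case = lower-score orientation.

    ``v10[i]`` is the fraction of controls a given case scores below (ties ½);
    ``v01[j]`` the fraction of cases a given control scores above.
    """
    diff = cases[:, None] - controls[None, :]
    win = (diff < 0).astype(float) + 0.5 * (diff == 0)
    return win.mean(axis=1), win.mean(axis=0)


def mann_whitney_auc(scores_cases, scores_controls) -> float:
    """AUC as the Mann-Whitney estimate P(case < control) + ½ P(tie)."""
    v10, _ = _placements(
        np.asarray(scores_cases, dtype=float), np.asarray(scores_controls, dtype=float)
    )
    return float(v10.mean())


def _cutoff_pair(threshold: float, pooled_sorted: np.ndarray) -> tuple[int, int]:
    above = pooled_sorted[pooled_sorted > threshold]
    if above.size:
        midpoint = 0.5 * (threshold + above[0])
    else:
        midpoint = threshold + 0.5
    a = int(np.floor(midpoint))
    return a, a + 1


def empirical_roc(scores_cases, scores_controls, level: float = 0.95) -> RocResult:
    """Empirical ROC curve, AUC and Youden-optimal cutoff.

    Cases are the impaired (lower-scoring) group; positivity is score ≤
    threshold.  When several thresholds tie on Youden's J the lowest cutoff
    (highest specificity) is chosen — the conservative referral rule.  The
    AUC confidence interval is the DeLong normal approximation.
    """
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both case and control groups must be non-empty")
    thresholds = np.unique(np.concatenate([cases, controls]))
    sens = (cases[:, None] <= thresholds[None, :]).mean(axis=0)
    spec = (controls[:, None] > thresholds[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (lowest) threshold on ties
    v10, v01 = _placements(cases, controls)
    auc = float(v10.mean())
    var = _delong_variance(v10, v01)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_threshold=float(thresholds[best]),
        optimal_cutoff=_cutoff_pair(float(thresholds[best]), thresholds),
        optimal_sensitivity=float(sens[best]),
        optimal_specificity=float(spec[best]),
        youden_j=float(j[best]),
        ci_lower=float(np.clip(auc - half, 0.0, 1.0)),
        ci_upper=float(np.clip(auc + half, 0.0, 1.0)),
        auc_variance=float(var),
        n_cases=cases.size,
        n_controls=controls.size,
    )


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def binormal_auc(mean_cases: float, sd_cases: float, mean_controls: float, sd_controls: float) -> float:
    """Analytic AUC of two normal score distributions: Φ(|Δμ| / √(σ₁² + σ₂²)).

    The degenerate zero-variance pair returns 1 for distinct means (perfect
    separation) and 0.5 for equal means.
    """
    spread = float(np.hypot(sd_cases, sd_controls))
    delta = abs(float(mean_controls) - float(mean_cases))
    if spread == 0.0:
        return 1.0 if delta > 0 else 0.5
    return float(stats.norm.cdf(delta / spread))


def delong_paired_test(scores_test_a, scores_test_b, case_labels) -> DelongResult:
    """DeLong's test for the difference of two paired AUCs.

    Both score vectors must be measured on the same subjects;
    ``case_labels`` marks the impaired group.  Returns the χ²(1) statistic
    (the squared z of the AUC difference over its placement-value standard
    error) with a two-sided p-value.
    """
    a = np.asarray(scores_test_a, dtype=float)
    b = np.asarray(scores_test_b, dtype=float)
    labels = np.asarray(case_labels, dtype=bool)
    if not (a.shape == b.shape == labels.shape):
        raise ValueError("score vectors and case labels must be aligned (same subjects)")
    m, n = int(labels.sum()), int((~labels).sum())
    if m < 2 or n < 2:
        raise ValueError("DeLong's test needs at least 2 cases and 2 controls")
    v10_a, v01_a = _placements(a[labels], a[~labels])
    v10_b, v01_b = _placements(b[labels], b[~labels])
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    var_diff = max(var_diff, 0.0)
    diff = auc_a - auc_b
    if var_diff == 0.0:
        z = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var_diff)
    chi2 = float(z**2) if np.isfinite(z) else np.inf
    p = float(stats.chi2.sf(chi2, 1)) if np.isfinite(chi2) else 0.0
    return DelongResult(
        auc_1=auc_a, auc_2=auc_b, variance_diff=var_diff,
        statistic=chi2, z=float(z), p_value=p,
    )


def auc_confidence_interval(roc: RocResult, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation AUC interval from the DeLong variance, clipped to [0, 1]."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(roc.auc_variance)
    return float(np.clip(roc.auc - half, 0.0, 1.0)), float(np.clip(roc.auc + half, 0.0, 1.0))


def sens_spec_at_cutoff(scores_cases, scores_controls, cutoff: float) -> tuple[float, float]:
    """Sensitivity and specificity of the rule "positive when score ≤ cutoff"."""
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    sens = float((cases <= cutoff).mean()) if cases.size else float("nan")
    spec = float((controls > cutoff).mean()) if controls.size else float("nan")
    return sens, spec
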