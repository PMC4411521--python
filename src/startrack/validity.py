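"""Construct-validity analysis of the four-arm crossover.

The scored trials are arranged into a complete subjects x conditions
matrix of integrated measures and pushed through the classical
within-subjects pipeline: Shapiro-Wilk normality per arm, Mauchly's
test of sphericity, a one-way repeated-measures ANOVA, and
Bonferroni-corrected pairwise post-hoc comparisons with family-wise
confidence intervals.

Mauchly's W is the determinant/trace ratio of the covariance of the
orthonormal within-subject contrasts,

    W = det(S) / (tr(S)/(k-1))**(k-1),

referred to a chi-square with k(k-1)/2 - 1 degrees of freedom through
the standard small-sample multiplier.  The ANOVA uses the one-way
within-subjects decomposition SS_total = SS_subjects + SS_conditions +
SS_error with F = MS_conditions / MS_error on (k-1, (n-1)(k-1)) df and
no sphericity correction.  Post-hoc p-values multiply the pairwise
least-significant-difference (paired t) p by the number of possible
pairs, capped at 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .integrated_measure import (
    ArmSummary,
    ScoredTrial,
    arm_summaries,
    integrated_measures,
)
from .reliability import shapiro_wilk
from .trial_model import VALIDITY_CONDITIONS, TrialRecord

__all__ = [
    "WithinSubjectMatrix",
    "PairwiseComparison",
    "ValidityResult",
    "build_matrix",
    "mauchly_test",
    "rm_anova",
    "bonferroni_posthoc",
    "analyze_validity",
]


@dataclass(frozen=True)
class WithinSubjectMatrix:
    """Complete n_subjects x k_conditions grid of integrated measures."""

    values: np.ndarray
    subjects: tuple[str, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, k = v.shape
        if n != len(self.subjects) or k != len(self.conditions):
            raise ValueError("values shape does not match subject/condition labels")
        if n < 2 or k < 2:
            raise ValueError(f"need n >= 2 subjects and k >= 2 conditions, got {n}x{k}")
        if not np.all(np.isfinite(v)):
            raise ValueError("matrix contains non-finite cells")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_conditions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PairwiseComparison:
    """One post-hoc contrast: mean difference a - b with CI and p-values."""

    pair: tuple[str, str]
    mean_difference: float
    ci_low: float
    ci_high: float
    p_uncorrected: float
    p_bonferroni: float


@dataclass(frozen=True)
class ValidityResult:
    """Full construct-validity analysis output."""

    arms: tuple[ArmSummary, ...]
    shapiro_p: dict[str, float]
    mauchly_W: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    anova_F: float
    anova_df: tuple[int, int]
    anova_p: float
    posthoc: tuple[PairwiseComparison, ...]

    def to_dict(self) -> dict:
        return {
            "arms": [
                {
                    "condition": a.condition,
                    "n": a.n,
                    "mean_im": a.mean_im,
                    "sd_im": a.sd_im,
                }
                for a in self.arms
            ],
            "shapiro_p": dict(self.shapiro_p),
            "mauchly_W": self.mauchly_W,
            "mauchly_chi2": self.mauchly_chi2,
            "mauchly_df": self.mauchly_df,
            "mauchly_p": self.mauchly_p,
            "anova_F": self.anova_F,
            "anova_df": list(self.anova_df),
            "anova_p": self.anova_p,
            "posthoc": [
                {
                    "pair": list(c.pair),
                    "mean_difference": c.mean_difference,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p_uncorrected": c.p_uncorrected,
                    "p_bonferroni": c.p_bonferroni,
                }
                for c in self.posthoc
            ],
        }


def build_matrix(scored: Sequence[ScoredTrial]) -> WithinSubjectMatrix:
    """Pivot scored trials into a complete within-subject matrix.

    Subjects become rows in stable id order; every subject must have
    exactly one trial per condition present in the data.
    """
    if not scored:
        raise ValueError("no scored trials")
    conditions = [c for c in VALIDITY_CONDITIONS if any(s.trial.condition == c for s in scored)]
    if not conditions:
        conditions = sorted({s.trial.condition for s in scored})
    cells: dict[tuple[str, str], float] = {}
    for s in scored:
        key = (s.trial.subject_id, s.trial.condition)
        if key in cells:
            raise ValueError(
                f"subject {key[0]!r} has duplicate trials in arm {key[1]!r}"
            )
        cells[key] = s.im
    subjects = sorted({s.trial.subject_id for s in scored})
    for subject in subjects:
        for cond in conditions:
            if (subject, cond) not in cells:
                raise ValueError(
                    f"incomplete crossover: subject {subject!r} is missing "
                    f"arm {cond!r}"
                )
    values = np.array(
        [[cells[(s, c)] for c in conditions] for s in subjects], dtype=float
    )
    return WithinSubjectMatrix(
        values=values, subjects=tuple(subjects), conditions=tuple(conditions)
    )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to the mean)."""
    # orthonormalize Helmert-style contrasts
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def mauchly_test(m: WithinSubjectMatrix) -> tuple[float, float, int, float]:
    """Mauchly's test of sphericity: (W, chi2, df, p).

    With k = 2 there is a single contrast, W = 1 and sphericity holds
    trivially (df = 0, p = 1).  Requires n > k so the contrast
    covariance is estimable.
    """
    n, k = m.n_subjects, m.k_conditions
    if n <= k:
        raise ValueError(f"Mauchly's test needs n > k (got n={n}, k={k})")
    p_dim = k - 1
    C = _orthonormal_contrasts(k)
    transformed = m.values @ C.T
    S = np.cov(transformed, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    det = float(np.linalg.det(S))
    trace = float(np.trace(S))
    if det <= 0 or trace <= 0:
        raise ValueError("degenerate data: singular within-subject contrast covariance")
    W = det / (trace / p_dim) ** p_dim
    df = k * (k - 1) // 2 - 1
    if df == 0:
        return 1.0, 0.0, 0, 1.0
    d = 1.0 - (2.0 * p_dim**2 + p_dim + 2.0) / (6.0 * p_dim * (n - 1.0))
    chi2 = -(n - 1.0) * d * math.log(W)
    p = float(stats.chi2.sf(chi2, df))
    return float(W), float(chi2), int(df), p


def rm_anova(m: WithinSubjectMatrix) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA: (F, df1, df2, p), uncorrected."""
    v = m.values
    n, k = v.shape
    grand = v.mean()
    ss_subjects = k * float(((v.mean(axis=1) - grand) ** 2).sum())
    ss_conditions = n * float(((v.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((v - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_conditions
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_error = ss_error / df2
    if ms_error <= 0:
        raise ValueError(
            "degenerate data: zero within-subject error variance, F undefined"
        )
    F = (ss_conditions / df1) / ms_error
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def bonferroni_posthoc(
    m: WithinSubjectMatrix, alpha: float = 0.05, adjust_ci: bool = True
) -> list[PairwiseComparison]:
    """All pairwise paired comparisons with Bonferroni correction.

    For each of the C = k(k-1)/2 unordered pairs (a, b), in the matrix's
    condition order: the difference of arm means (a - b), the paired-t
    (least significant difference) p multiplied by C and capped at 1,
    and a confidence interval on the difference — family-wise
    100(1-alpha)% (i.e. per-comparison 1 - alpha/C) when ``adjust_ci``,
    plain 100(1-alpha)% otherwise.
    """
    v = m.values
    n, k = v.shape
    C = k * (k - 1) // 2
    level = alpha / C if adjust_ci else alpha
    tcrit = stats.t.ppf(1.0 - level / 2.0, n - 1)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        d = v[:, i] - v[:, j]
        mean_d = float(d.mean())
        se = float(np.std(d, ddof=1) / math.sqrt(n))
        if se == 0:
            p_lsd = 1.0 if mean_d == 0 else 0.0
        else:
            p_lsd = float(stats.ttest_rel(v[:, i], v[:, j]).pvalue)
        out.append(
            PairwiseComparison(
                pair=(m.conditions[i], m.conditions[j]),
                mean_difference=mean_d,
                ci_low=mean_d - tcrit * se,
                ci_high=mean_d + tcrit * se,
                p_uncorrected=p_lsd,
                p_bonferroni=min(1.0, p_lsd * C),
            )
        )
    return out


def analyze_validity(
    trials: Sequence[TrialRecord], alpha: float = 0.05, adjust_ci: bool = True
) -> ValidityResult:
    """Run the full construct-validity pipeline on a crossover study.

    Pools all trials for ranking, pivots to the within-subject matrix,
    then: Shapiro-Wilk per arm, Mauchly, RM-ANOVA, Bonferroni post-hocs.
    """
    if any(t.phase != "validity" for t in trials):
        raise ValueError("analyze_validity expects validity-phase trials only")
    scored = integrated_measures(list(trials))
    matrix = build_matrix(scored)
    arms = arm_summaries(scored)
    shapiro_p = {
        cond: shapiro_wilk(matrix.values[:, i])[1]
        for i, cond in enumerate(matrix.conditions)
    }
    W, chi2, df, p_mauchly = mauchly_test(matrix)
    F, df1, df2, p_anova = rm_anova(matrix)
    posthoc = bonferroni_posthoc(matrix, alpha=alpha, adjust_ci=adjust_ci)
    return ValidityResult(
        arms=tuple(arms),
        shapiro_p=shapiro_p,
        mauchly_W=W,
        mauchly_chi2=chi2,
        mauchly_df=df,
        mauchly_p=p_mauchly,
        anova_F=F,
        anova_df=(df1, df2),
        anova_p=p_anova,
        posthoc=tuple(posthoc),
    )
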