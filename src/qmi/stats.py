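"""Repeated-measures inference over lesion stages, from first principles.

The longitudinal analysis compares, per quantitative parameter, the
normalized lesion-minus-control values at three stages (pre-lesional,
lesional, post-lesional) across lesions with a one-way repeated-measures
ANOVA, followed by post-hoc two-tailed paired-samples t tests.  Both are
implemented directly from their sums-of-squares / mean-difference
formulas (no sphericity correction, matching the reporting they mirror);
a Holm step-down adjustment is available as an option for the post-hoc
family but is off by default, since unadjusted post-hoc p-values are the
convention being reproduced.

Lesions are treated as independent units even when several arise in one
subject — a simplification that mirrors the per-lesion analysis being
reproduced and is a known limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "StageMatrix",
    "TestResult",
    "rm_anova_oneway",
    "rm_anova_sums_of_squares",
    "paired_t",
    "holm_adjust",
    "STAGES",
]

STAGES = ("pre-lesional", "lesional", "post-lesional")


@dataclass
class StageMatrix:
    """Complete-case lesions x stages matrix for one parameter."""

    data: np.ndarray  # (n_lesions, n_stages)
    parameter: str = ""
    stage_names: Tuple[str, ...] = STAGES

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("stage matrix must be 2D (lesions x stages)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 lesions")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stage matrix must be complete-case (no NaN)")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def k(self) -> int:
        return self.data.shape[1]


@dataclass
class TestResult:
    """A single test outcome: F or t statistic, df, two-tailed p."""

    statistic: float
    df: Tuple[int, int] | int
    p_two_tailed: float
    effect_direction: int = 0  # sign of the effect for t tests; 0 for F
    kind: str = "F"

    def __post_init__(self):
        if not (np.isnan(self.p_two_tailed)
                or 0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def rm_anova_sums_of_squares(data: np.ndarray) -> Dict[str, float]:
    """Sums-of-squares partition underlying the repeated-measures ANOVA."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    ss_total = float(((data - grand) ** 2).sum())
    ss_subj = float(k * ((data.mean(axis=1) - grand) ** 2).sum())
    ss_time = float(n * ((data.mean(axis=0) - grand) ** 2).sum())
    return {"ss_total": ss_total, "ss_subjects": ss_subj, "ss_time": ss_time,
            "ss_error": ss_total - ss_subj - ss_time}


def rm_anova_oneway(m: StageMatrix | np.ndarray) -> TestResult:
    """One-way repeated-measures ANOVA across stages.

    SS_total is partitioned into subject (lesion), time (stage) and
    error components; F = MS_time / MS_error on (k-1, (k-1)(n-1))
    degrees of freedom, without sphericity correction.  With zero error
    variance the p-value is reported as its limiting value (0 if there
    is a time effect, 1 otherwise) with a warning.
    """
    data = m.data if isinstance(m, StageMatrix) else np.asarray(m, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) matrix")
    n, k = data.shape
    ss = rm_anova_sums_of_squares(data)
    ss_time, ss_err = ss["ss_time"], ss["ss_error"]
    df_time, df_err = k - 1, (k - 1) * (n - 1)

    tiny = 1e-12 * max(ss["ss_total"], 1.0)
    if ss_err <= tiny:
        warnings.warn("zero within-lesion error variance; F degenerate, "
                      "p reported as limiting value")
        if ss_time <= tiny:
            return TestResult(0.0, (df_time, df_err), 1.0, kind="F")
        return TestResult(float("inf"), (df_time, df_err), 0.0, kind="F")

    f = (ss_time / df_time) / (ss_err / df_err)
    p = float(sps.f.sf(f, df_time, df_err))
    return TestResult(float(f), (df_time, df_err), p, kind="F")


def paired_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed paired-samples t test on d = a - b.

    t = mean(d) / (sd(d)/sqrt(n)) with df = n - 1.  Zero variance of d
    with a nonzero mean yields p -> 0 with a warning; an all-zero d
    gives t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1D samples with n >= 2")
    d = a - b
    n = d.size
    mean = d.mean()
    sd = d.std(ddof=1)
    direction = int(np.sign(mean))
    if sd == 0:
        if mean == 0:
            return TestResult(0.0, n - 1, 1.0, 0, kind="t")
        warnings.warn("zero variance of paired differences; p -> 0")
        return TestResult(float("inf") * np.sign(mean), n - 1, 0.0,
                          direction, kind="t")
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TestResult(float(t), n - 1, p, direction, kind="t")


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional post-hoc adjustment)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
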