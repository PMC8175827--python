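"""Test-retest reliability and convergent-validity statistics.

Relative reliability uses the two-way random-effects, single-measure,
absolute-agreement intraclass correlation ICC(2,1) (Shrout & Fleiss). For an
n-subject x k-occasion matrix with row (subject) mean square MSR, column
(occasion) mean square MSC and residual mean square MSE,

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with the companion F = MSR/MSE on (n-1), (n-1)(k-1) degrees of freedom.
ICC bands follow the convention used in validating this tool: high >= 0.70,
moderate in [0.50, 0.70), low < 0.50.

Absolute reliability chains SEM = SD x sqrt(1 - ICC) and
MDC = z x sqrt(2) x SEM with z = 1.65 (90% confidence, the default) or 1.96
(95%). %MDC expresses MDC against the occasion-1 group mean and is banded at
the 30% / 60% responsiveness cut-offs.

Systematic error between occasions uses the paired t-test; convergent validity
against reference assessments uses Pearson correlation with one-tailed
p-values by default (matching how such validity tables are reported).
Normality screening is delegated to the standard Shapiro-Wilk routine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ReliabilityResult", "ValidityResult", "MDC_Z",
    "two_way_anova_mean_squares", "icc_2_1", "classify_icc",
    "sem_from_sd_icc", "mdc_from_sem", "percent_mdc",
    "paired_t_test", "pearson_correlation", "normality_check",
]

#: z multipliers for the MDC confidence levels in common use.
MDC_Z = {0.90: 1.65, 0.95: 1.96}


@dataclass
class ReliabilityResult:
    """One metric x direction row of a test-retest reliability table."""

    metric_name: str
    direction: str
    icc: float
    icc_band: str
    icc_F: float
    icc_p: float
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    sem: float
    mdc: float
    pct_mdc: float | None
    pct_mdc_band: str | None
    paired_t: float
    paired_df: int
    paired_p: float
    n_subjects: int
    mdc_sd_basis: str = "test1"
    mdc_confidence: float = 0.90


@dataclass
class ValidityResult:
    """One CUE-metric x reference-score cell of a validity table."""

    cue_metric: str
    reference_score: str
    r: float
    p_one_tailed: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_one_tailed <= 0.05


# ---------------------------------------------------------------------------
# Two-way ANOVA and ICC(2,1)

def _as_matrix(matrix) -> np.ndarray:
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D subjects x occasions matrix, got shape {X.shape}")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 occasions, got {n} x {k}")
    if np.isnan(X).any():
        raise ValueError("matrix has missing cells; drop incomplete subjects first")
    return X


def two_way_anova_mean_squares(matrix) -> dict[str, float]:
    """Mean squares of the two-way decomposition without replication.

    Rows are subjects, columns occasions. Returns ``{'MSR', 'MSC', 'MSE'}``
    (rows / columns / residual), from the standard sums of squares with
    (n-1), (k-1) and (n-1)(k-1) degrees of freedom.
    """
    X = _as_matrix(matrix)
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    return {
        "MSR": ss_rows / (n - 1),
        "MSC": ss_cols / (k - 1),
        "MSE": max(ss_err, 0.0) / ((n - 1) * (k - 1)),
    }


def icc_2_1(matrix) -> dict[str, float]:
    """ICC(2,1): single-measure absolute agreement under the two-way random
    model, with its F test.

    Returns ``{'icc', 'F', 'p'}``; F = MSR/MSE on (n-1), (n-1)(k-1) df with an
    upper-tail p-value. Raises when the denominator is zero (a constant
    matrix has no agreement structure to estimate).
    """
    X = _as_matrix(matrix)
    n, k = X.shape
    ms = two_way_anova_mean_squares(X)
    msr, msc, mse = ms["MSR"], ms["MSC"], ms["MSE"]
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ZeroDivisionError("ICC(2,1) undefined: zero denominator (constant matrix?)")
    icc = (msr - mse) / denom
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        F = math.inf
        p = 0.0
    else:
        F = msr / mse
        p = float(stats.f.sf(F, df1, df2))
    return {"icc": float(icc), "F": float(F), "p": p}


def classify_icc(icc: float) -> str:
    """Band an ICC estimate: ``high`` >= 0.70, ``moderate`` in [0.50, 0.70),
    ``low`` < 0.50."""
    if icc > 1.0 + 1e-12:
        raise ValueError(f"icc must be <= 1, got {icc}")
    if icc >= 0.70:
        return "high"
    if icc >= 0.50:
        return "moderate"
    return "low"


# ---------------------------------------------------------------------------
# SEM / MDC chain

def sem_from_sd_icc(sd: float, icc: float) -> float:
    """Standard error of measurement: SEM = SD x sqrt(1 - ICC)."""
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if icc > 1.0 + 1e-12:
        raise ValueError(f"icc must be <= 1, got {icc}")
    return sd * math.sqrt(max(1.0 - icc, 0.0))


def mdc_from_sem(sem: float, confidence: float = 0.90) -> float:
    """Minimal detectable change: MDC = z x sqrt(2) x SEM, z = 1.65 (90%)
    or 1.96 (95%)."""
    if sem < 0:
        raise ValueError(f"sem must be >= 0, got {sem}")
    try:
        z = MDC_Z[confidence]
    except KeyError:
        raise ValueError(f"confidence must be one of {sorted(MDC_Z)}, got {confidence}")
    return z * math.sqrt(2.0) * sem


def percent_mdc(mdc: float, mean1: float) -> tuple[float, str]:
    """MDC as a percentage of the occasion-1 group mean, with its
    responsiveness band: '<30%' (responsive), '30-60%', or '>60%' (flagged)."""
    if mean1 == 0:
        raise ZeroDivisionError("%MDC undefined for zero group mean")
    pct = 100.0 * mdc / mean1
    if pct < 30.0:
        band = "<30%"
    elif pct <= 60.0:
        band = "30-60%"
    else:
        band = ">60%"
    return pct, band


# ---------------------------------------------------------------------------
# Paired t and Pearson r

def paired_t_test(x1, x2, tail: str = "two") -> dict[str, float]:
    """Paired t-test for systematic error between two occasions.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x1 - x2 and df = n - 1; p is
    two-tailed by default (no direction of drift is hypothesized). The
    degenerate case sd(d) = 0 with mean(d) = 0 (identical vectors) is flagged
    as t = 0, p = 1.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("x1 and x2 must be 1-D and the same length")
    n = a.size
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2, got {n}")
    d = a - b
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if float(d.mean()) == 0.0:
            return {"t": 0.0, "df": df, "p": 1.0, "degenerate": True}
        raise ZeroDivisionError("zero variance with nonzero mean difference")
    t = float(d.mean()) / (sd / math.sqrt(n))
    if tail == "two":
        p = 2.0 * float(stats.t.sf(abs(t), df))
    elif tail == "one":
        p = float(stats.t.sf(abs(t), df))
    else:
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    return {"t": t, "df": df, "p": p, "degenerate": False}


def pearson_correlation(x, y, tail: str = "one",
                        alternative: str = "greater") -> dict[str, float]:
    """Product-moment correlation with a t-based p-value.

    The p-value comes from t = r sqrt((n-2)/(1-r^2)) on n-2 df. ``tail='one'``
    (default) is a directional test whose direction is set by ``alternative``:
    ``'greater'`` (default; positive association hypothesized, the study's
    stated expectation for validity against the reference assessments),
    ``'less'``, or ``'observed'`` — the tail on the side of the observed r,
    which is how statistical packages print "Sig. (1-tailed)" next to
    correlations of either sign. Only the fixed-direction variants are proper
    tests with a Uniform(0,1) null p. ``tail='two'`` ignores ``alternative``.
    Constant inputs are rejected (r undefined).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = a.size
    if n < 3:
        raise ValueError(f"correlation needs n >= 3, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    am, bm = a - a.mean(), b - b.mean()
    r = float((am * bm).sum() / math.sqrt((am ** 2).sum() * (bm ** 2).sum()))
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        t = math.copysign(math.inf, r)
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    if tail == "two":
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    elif tail == "one":
        if alternative == "greater":
            p = float(stats.t.sf(t, n - 2))
        elif alternative == "less":
            p = float(stats.t.cdf(t, n - 2))
        elif alternative == "observed":
            p = float(stats.t.sf(abs(t), n - 2))
        else:
            raise ValueError(
                f"alternative must be 'greater', 'less' or 'observed', "
                f"got {alternative!r}")
    else:
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    return {"r": r, "p": p, "n": n}


def normality_check(values) -> dict[str, float]:
    """Shapiro-Wilk screen (delegated to the standard routine), reported
    alongside reliability results rather than gating them."""
    v = np.asarray(values, dtype=float)
    w, p = stats.shapiro(v)
    return {"W": float(w), "p": float(p), "n": int(v.size)}
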