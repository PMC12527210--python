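"""Pre-registered statistics: one-tailed t-tests, effect sizes, default
JZS Bayes factors with robustness sweeps, Pearson correlations, and a
noncentral-t sample-size solver.

Conventions
-----------
* t-tests report a *one-tailed* p-value in the stated direction
  (``alternative`` is ``"greater"`` or ``"less"``); mirrored data with the
  flipped alternative give identical p.
* Effect sizes: d_z (mean difference / SD of differences) for one-sample and
  paired designs, Cohen's d from the pooled SD for two-sample designs.
* Bayes factors are two-sided default JZS factors (Cauchy prior on the
  standardized effect, scale 0.707 unless overridden) — the convention of
  standard Bayesian t-test software.  BF01 = 1/BF10 by definition.
* Degenerate inputs (zero variance with a nonzero numerator) do not raise;
  they return a :class:`TestResult` whose ``error`` field is set, so
  pipelines can report rather than crash.  Zero variance *and* zero
  numerator is the exactly-null sample: t = 0, p = 0.5 one-tailed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "TestResult",
    "RobustnessCurve",
    "one_sample_t",
    "paired_t",
    "two_sample_t",
    "jzs_bf10",
    "bf_robustness",
    "pearson_r",
    "required_n_paired",
    "DEFAULT_CAUCHY_SCALE",
]

DEFAULT_CAUCHY_SCALE = 0.707

_ALTERNATIVES = ("greater", "less")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one t-test: statistic, df, one-tailed p, effect size and
    JZS Bayes factor.  ``df`` may be non-integer for the unequal-variance
    form.  ``error`` is set (and the numeric fields are NaN) for degenerate
    inputs such as zero-variance samples."""

    statistic: float
    df: float
    p_one_tailed: float
    effect_size: float
    bf10: float
    alternative: str
    n1: int
    n2: int | None = None
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE
    error: str | None = None

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass(frozen=True)
class RobustnessCurve:
    """JZS Bayes factor as a function of the Cauchy prior scale."""

    prior_scales: tuple[float, ...]
    bf10_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.prior_scales) != len(self.bf10_values):
            raise ValueError("prior_scales and bf10_values length mismatch")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def _one_tailed_p(t: float, df: float, alternative: str) -> float:
    if alternative == "greater":
        return float(stats.t.sf(t, df))
    return float(stats.t.cdf(t, df))


def _degenerate(alternative: str, n1: int, n2: int | None, msg: str) -> TestResult:
    return TestResult(
        statistic=math.nan,
        df=math.nan,
        p_one_tailed=math.nan,
        effect_size=math.nan,
        bf10=math.nan,
        alternative=alternative,
        n1=n1,
        n2=n2,
        error=msg,
    )


def one_sample_t(
    values: Sequence[float],
    mu0: float = 0.0,
    alternative: str = "greater",
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
    compute_bf10: bool = True,
) -> TestResult:
    """One-sample t-test of ``mean(values)`` against ``mu0``.

    t = (mean − mu0)/(sd/√n), df = n − 1, d_z = (mean − mu0)/sd.
    ``compute_bf10=False`` skips the Bayes-factor quadrature (bf10 is NaN),
    useful in tight simulation loops that only need the frequentist part.
    """
    _check_alternative(alternative)
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d sample of size >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    scale = max(abs(mean), abs(mu0), 1.0)
    if sd <= 1e-12 * scale:  # constant sample up to float rounding
        if abs(mean - mu0) <= 1e-9 * scale:
            t = 0.0
            d_z = 0.0
        else:
            return _degenerate(alternative, n, None, "zero variance")
    else:
        t = (mean - mu0) / (sd / math.sqrt(n))
        d_z = (mean - mu0) / sd
    return TestResult(
        statistic=t,
        df=float(df),
        p_one_tailed=_one_tailed_p(t, df, alternative),
        effect_size=d_z,
        bf10=jzs_bf10(t, n, cauchy_scale=cauchy_scale) if compute_bf10 else math.nan,
        alternative=alternative,
        n1=n,
        cauchy_scale=cauchy_scale,
    )


def paired_t(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
    compute_bf10: bool = True,
) -> TestResult:
    """Paired t-test on x − y (one-sample test of the differences against 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return one_sample_t(x - y, 0.0, alternative, cauchy_scale, compute_bf10)


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
    unequal_variance: bool = False,
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
    compute_bf10: bool = True,
) -> TestResult:
    """Independent-samples t-test of mean(x) − mean(y).

    Pooled-variance Student form (df = n1 + n2 − 2) by default; the
    unequal-variance (Welch) form uses the Welch–Satterthwaite df.  Cohen's d
    is computed from the pooled SD in both cases.  The Bayes factor is the
    default two-sided JZS factor for the two-sample design.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs size >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    n1, n2 = x.size, y.size
    m1, m2 = float(x.mean()), float(y.mean())
    v1, v2 = float(x.var(ddof=1)), float(y.var(ddof=1))
    diff = m1 - m2
    scale = max(abs(m1), abs(m2), 1.0)
    var_floor = (1e-12 * scale) ** 2
    if unequal_variance and (v1 <= var_floor or v2 <= var_floor):
        return _degenerate(alternative, n1, n2, "zero variance in a group")
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled_var <= var_floor:
        if abs(diff) <= 1e-9 * scale:
            t, df, d = 0.0, float(n1 + n2 - 2), 0.0
        else:
            return _degenerate(alternative, n1, n2, "zero variance")
    elif unequal_variance:
        se2 = v1 / n1 + v2 / n2
        t = diff / math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        d = diff / math.sqrt(pooled_var)
    else:
        t = diff / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
        d = diff / math.sqrt(pooled_var)
    return TestResult(
        statistic=t,
        df=df,
        p_one_tailed=_one_tailed_p(t, df, alternative),
        effect_size=d,
        bf10=jzs_bf10(t, n1, n2, cauchy_scale=cauchy_scale) if compute_bf10 else math.nan,
        alternative=alternative,
        n1=n1,
        n2=n2,
        cauchy_scale=cauchy_scale,
    )


class IntegrationError(RuntimeError):
    """Raised when the Bayes-factor quadrature fails to converge."""


def jzs_bf10(
    t: float,
    n1: int,
    n2: int | None = None,
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
) -> float:
    """Default JZS Bayes factor BF10 for a t statistic.

    The marginal likelihood under the alternative places a Cauchy(0, scale)
    prior on the standardized effect δ and integrates the noncentral-t
    density of the observed statistic over it:

        BF10 = ∫ f_nct(t; df, δ·√n_eff) dCauchy(δ) / f_t(t; df)

    with n_eff = n for the one-sample/paired design and n1·n2/(n1+n2) for
    the two-sample design (df = n − 1 and n1 + n2 − 2 respectively).  The
    integral is evaluated by adaptive quadrature after the substitution
    δ = scale·tan(θ), which maps the Cauchy prior to a uniform on
    (−π/2, π/2); absolute tolerance 1e-10.
    """
    if cauchy_scale <= 0:
        raise ValueError("cauchy_scale must be > 0")
    if n2 is None:
        if n1 < 2:
            raise ValueError("need n >= 2")
        n_eff = float(n1)
        df = n1 - 1
    else:
        if n1 < 2 or n2 < 2:
            raise ValueError("need n1, n2 >= 2")
        n_eff = n1 * n2 / (n1 + n2)
        df = n1 + n2 - 2
    sqrt_neff = math.sqrt(n_eff)
    r = cauchy_scale

    def integrand(theta: float) -> float:
        delta = r * math.tan(theta)
        return stats.nct.pdf(t, df, delta * sqrt_neff) / math.pi

    # The integrand peaks near the maximum-likelihood effect; passing that
    # location as a breakpoint keeps adaptive quadrature from stepping over
    # the (narrow, for large |t|) spike.
    peak = math.atan((t / sqrt_neff) / r)
    num, abserr = integrate.quad(
        integrand,
        -math.pi / 2,
        math.pi / 2,
        points=[peak],
        epsabs=1e-10,
        epsrel=1e-9,
        limit=400,
    )
    null_pdf = float(stats.t.pdf(t, df))
    if not math.isfinite(num) or num <= 0 or abserr > max(1e-8, 1e-6 * num):
        raise IntegrationError(
            f"Bayes-factor quadrature failed (t={t}, df={df}, scale={r})"
        )
    return num / null_pdf


def bf_robustness(
    t: float,
    n1: int,
    n2: int | None = None,
    scales: Sequence[float] = (),
) -> RobustnessCurve:
    """Evaluate the JZS Bayes factor across a grid of Cauchy prior scales."""
    scales = tuple(float(s) for s in scales)
    if not scales:
        raise ValueError("scales grid must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("all prior scales must be > 0")
    values = []
    for s in scales:
        try:
            values.append(jzs_bf10(t, n1, n2, cauchy_scale=s))
        except IntegrationError as exc:
            raise IntegrationError(f"scale {s}: {exc}") from exc
    return RobustnessCurve(prior_scales=scales, bf10_values=tuple(values))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-tailed t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _paired_power(n: int, d_z: float, alpha: float, tails: int) -> float:
    df = n - 1
    ncp = d_z * math.sqrt(n)
    t_crit = stats.t.isf(alpha / tails, df)
    power = float(stats.nct.sf(t_crit, df, ncp))
    if tails == 2:
        power += float(stats.nct.cdf(-t_crit, df, ncp))
    return power


def required_n_paired(
    d_z: float,
    power: float = 0.80,
    alpha: float = 0.05,
    tails: int = 2,
    max_n: int = 10_000_000,
) -> int:
    """Smallest n reaching the target power for a paired/one-sample t-test.

    Power is exact under the noncentral t distribution with noncentrality
    d_z·√n and df = n − 1 (the standard sample-size computation for a
    within-participants comparison).
    """
    if d_z <= 0:
        raise ValueError("d_z must be > 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if not (0 < power < 1):
        raise ValueError("power must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    lo, hi = 2, 2
    while _paired_power(hi, d_z, alpha, tails) < power:
        lo, hi = hi, hi * 2
        if hi > max_n:
            raise ValueError(f"power {power} unattainable below n = {max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if _paired_power(mid, d_z, alpha, tails) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi
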