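"""Bayes factors and design analysis for the cohort-level questions.

Implemented here:

* **Proportion Bayes factor** — binomial test of ``y`` successes in ``N``
  trials against a point null ``p0``, with a logistic prior (scale ``r``,
  default 0.5) on the log-odds displacement ``psi``:
  ``logit(p) = logit(p0) + psi``.  ``BF10`` is the ratio of the marginal
  binomial likelihood under the prior (optionally truncated to one side and
  renormalised) to the likelihood at ``p0``.  This is the construction of
  the standard R proportion Bayes factor; note that published analyses of
  this design report the *two-sided* variant.
* **Chi-square goodness-of-fit** for one proportion (df = 1).
* **JZS t-test Bayes factor** — one-sample/paired BF with a Cauchy prior on
  the standardised effect, optionally truncated for a directional test.
* **Bayes Factor Design Analysis** — fixed-n (and a sequential variant)
  simulation of study outcomes classified by evidence boundaries
  (default 6 and 1/6).
* **Required sample size** for a paired t-test via the noncentral-t power
  function.
* **Contingency Bayes factor** (Dirichlet priors) for two-category counts
  or a 2x2 table; its mapping onto the design's quadrant comparison is
  interpretation-dependent and is labelled as such.

All quadratures target a relative error below 1e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate, optimize, special, stats

SQRT2_OVER_2 = math.sqrt(2.0) / 2.0


# ---------------------------------------------------------------------------
# proportion Bayes factor


@dataclass(frozen=True)
class ProportionTestSpec:
    y: int
    N: int
    p0: float
    side: str = "greater"
    prior_scale: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.y <= self.N:
            raise ValueError("require 0 <= y <= N")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie strictly inside (0, 1)")
        if self.side not in ("greater", "less", "two-sided"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.prior_scale <= 0:
            raise ValueError("prior scale must be > 0")


def proportion_bf(
    y: int, N: int, p0: float, side: str = "greater", r: float = 0.5
) -> float:
    """BF10 for a binomial proportion against a point null.

    Under H1 the log-odds displacement ``psi ~ Logistic(0, r)``; one-sided
    tests truncate and renormalise the prior.  Integration is performed in
    the prior's CDF domain (exact change of variables), which is stable for
    any ``r > 0``.
    """
    spec = ProportionTestSpec(y=y, N=N, p0=p0, side=side, prior_scale=r)
    logit0 = special.logit(spec.p0)

    def integrand(u: float) -> float:
        psi = stats.logistic.ppf(u, scale=r)
        p = special.expit(logit0 + psi)
        return float(stats.binom.pmf(y, N, p))

    if side == "two-sided":
        lo, hi, norm = 0.0, 1.0, 1.0
    elif side == "greater":
        lo, hi, norm = 0.5, 1.0, 2.0
    else:
        lo, hi, norm = 0.0, 0.5, 2.0
    num, _ = integrate.quad(integrand, lo, hi, epsabs=0.0, epsrel=1e-9, limit=500)
    return norm * num / float(stats.binom.pmf(y, N, p0))


def chi_square_gof(y: int, N: int, p0: float) -> float:
    """One-proportion chi-square statistic (df = 1)."""
    if N <= 0:
        raise ValueError("N must be > 0")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    e1, e0 = N * p0, N * (1.0 - p0)
    return (y - e1) ** 2 / e1 + ((N - y) - e0) ** 2 / e0


# ---------------------------------------------------------------------------
# JZS t-test Bayes factor


@dataclass(frozen=True)
class TTestBFSpec:
    side: str = "greater"  # or "two-sided"
    cauchy_scale: float = SQRT2_OVER_2

    def __post_init__(self) -> None:
        if self.side not in ("greater", "two-sided"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.cauchy_scale <= 0:
            raise ValueError("cauchy scale must be > 0")


def _jzs_nodes(side: str, scale: float, n_nodes: int = 200):
    """Gauss-Legendre nodes/weights for the Cauchy prior on the effect,
    via the substitution ``delta = scale * tan(u)`` (prior density becomes
    ``1/pi`` on ``u``)."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    if side == "greater":
        lo, hi, norm = 0.0, math.pi / 2, 2.0
    else:
        lo, hi, norm = -math.pi / 2, math.pi / 2, 1.0
    u = lo + (hi - lo) * (x + 1) / 2
    wu = w * (hi - lo) / 2 * norm / math.pi
    return scale * np.tan(u), wu


def jzs_ttest_bf(
    t: float | np.ndarray,
    n: int,
    side: str = "greater",
    cauchy_scale: float = SQRT2_OVER_2,
) -> float | np.ndarray:
    """JZS BF10 for a one-sample (paired-differences) t statistic.

    Marginal likelihood of ``t`` under ``delta ~ Cauchy(0, scale)`` (halved
    and doubled for a directional test) divided by the central-t likelihood
    at ``delta = 0``.  Accepts a scalar or an array of t values.
    """
    TTestBFSpec(side=side, cauchy_scale=cauchy_scale)
    if n < 2:
        raise ValueError("n must be >= 2")
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    df = n - 1
    delta, w = _jzs_nodes(side, cauchy_scale)
    with np.errstate(over="ignore", under="ignore"):
        dens = stats.nct.pdf(ts[:, None], df, delta[None, :] * math.sqrt(n))
    num = np.nan_to_num(dens, nan=0.0) @ w
    bf = num / stats.t.pdf(ts, df)
    return float(bf[0]) if np.isscalar(t) else bf


# ---------------------------------------------------------------------------
# Bayes Factor Design Analysis


@dataclass(frozen=True)
class DesignAnalysisSpec:
    effect_d: float
    n: int
    reps: int = 10_000
    upper_bound: float = 6.0
    lower_bound: float = 1.0 / 6.0
    side: str = "greater"
    cauchy_scale: float = SQRT2_OVER_2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.upper_bound > 1 > self.lower_bound >= 0:
            raise ValueError("require upper_bound > 1 > lower_bound >= 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


class DesignAnalysisResult(NamedTuple):
    p_evidence_h1: float
    p_inconclusive: float
    p_evidence_h0: float


def bfda_fixed_n(spec: DesignAnalysisSpec) -> DesignAnalysisResult:
    """Fixed-n BFDA: simulate ``reps`` studies of ``n`` paired differences
    drawn from ``Normal(d, 1)``, compute the JZS BF10 for each, and classify
    against the evidence boundaries.  Deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    x = rng.normal(spec.effect_d, 1.0, size=(spec.reps, spec.n))
    ts = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(spec.n))
    bfs = jzs_ttest_bf(ts, spec.n, side=spec.side, cauchy_scale=spec.cauchy_scale)
    h1 = float(np.mean(bfs >= spec.upper_bound))
    h0 = float(np.mean(bfs <= spec.lower_bound))
    return DesignAnalysisResult(h1, 1.0 - h1 - h0, h0)


def bfda_sequential(
    effect_d: float,
    n_min: int = 20,
    n_max: int = 100,
    step: int = 1,
    reps: int = 1000,
    upper_bound: float = 6.0,
    lower_bound: float = 1.0 / 6.0,
    side: str = "greater",
    cauchy_scale: float = SQRT2_OVER_2,
    seed: int = 0,
) -> dict:
    """Sequential-design variant: look at the BF from ``n_min`` onward in
    steps of ``step`` and stop at the first boundary hit or at ``n_max``.

    Returns hit proportions and the mean stopping sample size.  Boundary
    crossing is evaluated through precomputed t thresholds (the one-sided
    JZS BF is monotone in t), which is exact and fast.
    """
    ns = list(range(n_min, n_max + 1, step))
    thresholds = {}
    for n in ns:
        bf = lambda t: jzs_ttest_bf(t, n, side=side, cauchy_scale=cauchy_scale)
        thresholds[n] = (
            optimize.brentq(lambda t: bf(t) - lower_bound, -30, 30),
            optimize.brentq(lambda t: bf(t) - upper_bound, -30, 30),
        )
    rng = np.random.default_rng(seed)
    outcomes = {"h1": 0, "h0": 0, "inconclusive": 0}
    stop_ns = []
    for _ in range(reps):
        x = rng.normal(effect_d, 1.0, n_max)
        outcome = "inconclusive"
        stop_n = n_max
        for n in ns:
            xx = x[:n]
            t = xx.mean() / (xx.std(ddof=1) / math.sqrt(n))
            lo, hi = thresholds[n]
            if t >= hi:
                outcome, stop_n = "h1", n
                break
            if t <= lo:
                outcome, stop_n = "h0", n
                break
        outcomes[outcome] += 1
        stop_ns.append(stop_n)
    return {
        "p_evidence_h1": outcomes["h1"] / reps,
        "p_evidence_h0": outcomes["h0"] / reps,
        "p_inconclusive": outcomes["inconclusive"] / reps,
        "mean_stopping_n": float(np.mean(stop_ns)),
    }


# ---------------------------------------------------------------------------
# frequentist power / required n


def power_paired_t(
    n: int, d: float, alpha: float = 0.05, side: str = "one-tailed"
) -> float:
    """Power of the one-sample t-test on paired differences at effect d."""
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    ncp = d * math.sqrt(n)
    if side in ("one-tailed", "greater"):
        crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    if side in ("two-tailed", "two-sided"):
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
    raise ValueError(f"unknown side {side!r}")


def required_n_paired_t(
    mean_diff: float,
    sd_diff: float,
    alpha: float = 0.05,
    power: float = 0.80,
    side: str = "one-tailed",
    n_max: int = 1_000_000,
) -> int:
    """Smallest n whose noncentral-t power reaches the target."""
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie in (0, 1)")
    if sd_diff <= 0:
        raise ValueError("sd_diff must be > 0")
    d = mean_diff / sd_diff
    for n in range(2, n_max + 1):
        if power_paired_t(n, d, alpha, side) >= power:
            return n
    raise RuntimeError("no n found below n_max")


# ---------------------------------------------------------------------------
# contingency Bayes factor (interpretation-dependent)


class ContingencyBFResult(NamedTuple):
    bf10: float
    formulation: str
    side: str
    note: str


_AMBIGUITY_NOTE = (
    "interpretation-dependent: the mapping of the quadrant comparison onto a "
    "contingency-table vs proportion-style Bayes factor is not uniquely "
    "determined"
)


def _beta_posterior_order_prob(a1: float, b1: float, a2: float, b2: float) -> float:
    """P(p1 > p2) for independent Beta posteriors, by quadrature."""
    f = lambda p: stats.beta.pdf(p, a1, b1) * stats.beta.cdf(p, a2, b2)
    val, _ = integrate.quad(f, 0.0, 1.0, epsabs=0.0, epsrel=1e-9, limit=500)
    return val


def contingency_bf(
    counts, prior_concentration: float = 1.0, side: str | None = None
) -> ContingencyBFResult:
    """Dirichlet-prior Bayes factor for two-category counts or a 2x2 table.

    * A length-2 vector ``(y1, y2)`` is treated as one binomial sample
      tested against equiprobability (``p = 1/2``) with a
      ``Beta(a, a)`` prior under H1.
    * A 2x2 table is treated as two independent binomials (rows fixed),
      comparing independent ``Beta(a, a)`` priors (H1) against a shared
      one (H0) — the independent-multinomial construction with Dirichlet
      priors.

    ``side='greater'`` multiplies by the posterior probability of the
    ordering (first category/row larger) relative to its prior probability
    of one half.  The result is labelled interpretation-dependent.
    """
    a = prior_concentration
    if a <= 0:
        raise ValueError("prior concentration must be > 0")
    arr = np.asarray(counts)
    if (arr < 0).any() or arr.sum() == 0:
        raise ValueError("counts must be nonnegative and not all zero")

    if arr.shape == (2,):
        y1, y2 = (int(v) for v in arr)
        n = y1 + y2
        log_bf = (
            special.betaln(y1 + a, y2 + a)
            - special.betaln(a, a)
            + n * math.log(2.0)
        )
        bf = math.exp(log_bf)
        if side == "greater":
            post = float(stats.beta.sf(0.5, y1 + a, y2 + a))
            bf *= post / 0.5
        formulation = "binomial-vs-half"
    elif arr.shape == (2, 2):
        (y1, f1), (y2, f2) = arr
        log_bf = (
            special.betaln(y1 + a, f1 + a)
            + special.betaln(y2 + a, f2 + a)
            - special.betaln(a, a)
            - special.betaln(y1 + y2 + a, f1 + f2 + a)
        )
        bf = math.exp(log_bf)
        if side == "greater":
            post = _beta_posterior_order_prob(y1 + a, f1 + a, y2 + a, f2 + a)
            bf *= post / 0.5
        formulation = "independent-multinomial"
    else:
        raise ValueError("counts must be a 2-vector or a 2x2 table")

    return ContingencyBFResult(
        bf10=float(bf),
        formulation=formulation,
        side=side or "two-sided",
        note=_AMBIGUITY_NOTE,
    )
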