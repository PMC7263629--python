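"""Type I isobolographic engine for fixed-ratio two-drug mixtures.

Under Loewe additivity a mixture in which drug A contributes a fraction
``f`` of the additive effect and drug B the remaining ``1 - f`` has the
theoretical median effective total dose

    ED50_add = f * ED50_A + (1 - f) * ED50_B,

with SEM propagated as ``sqrt(f^2 sem_A^2 + (1-f)^2 sem_B^2)`` and the
conventional effective sample size ``n_add = n_A + n_B - 4``.  This single
additive point is only meaningful when the two log-probit lines are
parallel.  When they are not, the additive region is bounded by two curved
isoboles obtained by dose equivalence: converting one drug into equivalents
of the other through the ratio of probit slopes,

    d_A / ED50_A + (d_B / ED50_B) ** (b_B / b_A) = 1     (one bound)
    (d_A / ED50_A) ** (b_A / b_B) + d_B / ED50_B = 1     (the mirror bound)

each of which intersects the fixed-ratio ray at one total dose; the smaller
intersection is the lower additive ED50, the larger the upper.  At f = 0.5
the two bounds are exactly symmetric about the straight-line additive value.

The experimentally fitted mixture ED50 is compared with the additive
prediction by an unpaired t test with Welch correction on the two estimates'
SEMs, and the interaction index I = ED50_exp / ED50_add (lower bound for
non-parallel pairs) quantifies interaction strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .probit import ProbitFit

__all__ = [
    "MixtureDesign",
    "AdditivePrediction",
    "InteractionResult",
    "PowerReport",
    "additive_parallel",
    "additive_nonparallel",
    "interaction_index",
    "compare_exp_vs_add",
    "compromise_power",
    "therapeutic_index",
    "mixture_component_doses",
]


@dataclass(frozen=True)
class MixtureDesign:
    """A fixed-ratio two-drug mixture ray.

    ``fixed_fraction_f`` is the fraction of the additive effect contributed
    by agent A; 0.5 encodes the equi-effective "1:1" design.  The component
    mg/kg ratio along the ray is ``f*ED50_a : (1-f)*ED50_b``.
    """

    agent_a: str
    agent_b: str
    ed50_a: float
    ed50_b: float
    fixed_fraction_f: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.fixed_fraction_f < 1.0:
            raise ValueError("fixed_fraction_f must lie in (0, 1)")
        if self.ed50_a <= 0 or self.ed50_b <= 0:
            raise ValueError("ED50s must be positive")

    @property
    def component_dose_ratio(self) -> float:
        """mg/kg of A per mg/kg of B along the ray."""
        f = self.fixed_fraction_f
        return (f * self.ed50_a) / ((1.0 - f) * self.ed50_b)

    @property
    def additive_total(self) -> float:
        f = self.fixed_fraction_f
        return f * self.ed50_a + (1.0 - f) * self.ed50_b

    @property
    def weight_a(self) -> float:
        """Fraction of any total dose on this ray that is drug A."""
        f = self.fixed_fraction_f
        return f * self.ed50_a / self.additive_total


@dataclass(frozen=True)
class AdditivePrediction:
    """Theoretical Loewe-additive ED50 for a fixed-ratio mixture.

    ``kind == "parallel"``: a single ``ed50_add`` with ``sem_add``.
    ``kind == "nonparallel"``: ``lower_ed50_add``/``upper_ed50_add`` with
    ``sem_lower``/``sem_upper``.  ``n_add = n_a + n_b - 4`` in both cases.
    """

    kind: Literal["parallel", "nonparallel"]
    n_add: int
    ed50_add: float | None = None
    sem_add: float | None = None
    lower_ed50_add: float | None = None
    upper_ed50_add: float | None = None
    sem_lower: float | None = None
    sem_upper: float | None = None

    @property
    def reference_ed50(self) -> float:
        """The value the experimental ED50 is compared against."""
        if self.kind == "parallel":
            return self.ed50_add
        return self.lower_ed50_add

    @property
    def reference_sem(self) -> float:
        if self.kind == "parallel":
            return self.sem_add
        return self.sem_lower


@dataclass(frozen=True)
class InteractionResult:
    """Experimental-vs-additive comparison for one mixture."""

    design: MixtureDesign | None
    ed50_exp: float
    sem_exp: float
    n_exp: int
    additive: AdditivePrediction
    t_statistic: float
    df: float
    p_value: float
    interaction_index: float
    classification: Literal["synergy", "additivity", "antagonism"]


@dataclass(frozen=True)
class PowerReport:
    """Outcome of a compromise power analysis (beta/alpha ratio fixed)."""

    effect_size_d: float
    implied_alpha: float
    implied_power: float
    beta_alpha_ratio_q: float
    df: float
    critical_t: float


def _n_add(n_a: int, n_b: int) -> int:
    return n_a + n_b - 4


def additive_parallel(
    fit_a: ProbitFit, fit_b: ProbitFit, f: float = 0.5
) -> AdditivePrediction:
    """Straight-line additive ED50 for parallel log-probit lines.

    ``ed50_add = f*ED50_a + (1-f)*ED50_b`` with SEM combined in quadrature
    weighted by the effect fractions.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie in (0, 1)")
    ed50 = f * fit_a.ed50 + (1.0 - f) * fit_b.ed50
    sem = math.sqrt((f * fit_a.sem_ed50) ** 2 + ((1.0 - f) * fit_b.sem_ed50) ** 2)
    return AdditivePrediction(
        kind="parallel",
        ed50_add=ed50,
        sem_add=sem,
        n_add=_n_add(fit_a.n_effective, fit_b.n_effective),
    )


def _ray_intersection(
    ed50_a: float, ed50_b: float, f: float, rho: float, rtol: float = 1e-10
) -> float:
    """Total dose where the dose-equivalence isobole meets the fixed ray.

    The isobole is ``u + v**rho = 1`` with ``u = d_a/ED50_a`` and
    ``v = d_b/ED50_b``; along the ray ``u = f*s`` and ``v = (1-f)*s`` with
    ``s = T / (f*ED50_a + (1-f)*ED50_b)``.  Solved by bracketed root finding
    to relative tolerance ``rtol``.
    """
    E = f * ed50_a + (1.0 - f) * ed50_b

    def g(s: float) -> float:
        return f * s + ((1.0 - f) * s) ** rho - 1.0

    hi = 1.0 / f  # first term alone reaches 1 here
    lo = 1e-12
    if g(hi) < 0:  # numerically defensive; g is increasing in s
        raise ArithmeticError("no additive-isobole intersection on the ray")
    s_root = optimize.brentq(g, lo, hi, rtol=rtol, xtol=1e-300)
    T = s_root * E
    if not 0.0 < T <= ed50_a + ed50_b:
        raise ArithmeticError(
            f"additive intersection {T} outside (0, ED50_a + ED50_b]"
        )
    return T


def additive_nonparallel(
    fit_a: ProbitFit, fit_b: ProbitFit, f: float = 0.5
) -> AdditivePrediction:
    """Lower and upper additive ED50 bounds for non-parallel lines.

    Each bound converts one drug into equivalents of the other using the
    ratio of probit slopes as the dose-equivalence exponent, and is
    intersected with the fixed-ratio ray.  SEMs are propagated from the
    single-drug SEMs by a numerical delta method (slopes held fixed).
    When the slopes are equal both bounds coincide with the parallel value.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie in (0, 1)")
    if fit_a.slope_b <= 0 or fit_b.slope_b <= 0:
        raise ValueError("both fitted slopes must be positive")
    rho1 = fit_b.slope_b / fit_a.slope_b
    rho2 = fit_a.slope_b / fit_b.slope_b

    def totals(A: float, B: float) -> tuple[float, float]:
        t1 = _ray_intersection(A, B, f, rho1)
        # mirror bound: swap roles of the drugs (and of f)
        t2 = _ray_intersection(B, A, 1.0 - f, rho2)
        return t1, t2

    t1, t2 = totals(fit_a.ed50, fit_b.ed50)

    # delta-method SEMs: central differences in each single-drug ED50
    def grad(which: int) -> tuple[float, float]:
        gs = []
        for i, (val, sem) in enumerate(
            [(fit_a.ed50, fit_a.sem_ed50), (fit_b.ed50, fit_b.sem_ed50)]
        ):
            h = 1e-6 * val
            args_hi = [fit_a.ed50, fit_b.ed50]
            args_lo = [fit_a.ed50, fit_b.ed50]
            args_hi[i] += h
            args_lo[i] -= h
            f_hi = totals(*args_hi)[which]
            f_lo = totals(*args_lo)[which]
            gs.append((f_hi - f_lo) / (2.0 * h))
        return gs[0], gs[1]

    sems = []
    for which in (0, 1):
        ga, gb = grad(which)
        sems.append(
            math.sqrt((ga * fit_a.sem_ed50) ** 2 + (gb * fit_b.sem_ed50) ** 2)
        )

    (lower, sem_lower), (upper, sem_upper) = sorted(zip((t1, t2), sems))
    return AdditivePrediction(
        kind="nonparallel",
        lower_ed50_add=lower,
        upper_ed50_add=upper,
        sem_lower=sem_lower,
        sem_upper=sem_upper,
        n_add=_n_add(fit_a.n_effective, fit_b.n_effective),
    )


def interaction_index(ed50_exp: float, additive: AdditivePrediction) -> float:
    """I = ED50_exp / ED50_add (lower additive bound for non-parallel pairs)."""
    ref = additive.reference_ed50
    if ref is None or ref <= 0:
        raise ValueError("additive reference ED50 must be positive")
    if ed50_exp <= 0:
        raise ValueError("ed50_exp must be positive")
    return ed50_exp / ref


def compare_exp_vs_add(
    ed50_exp: float,
    sem_exp: float,
    n_exp: int,
    additive: AdditivePrediction,
    alpha: float = 0.05,
    design: MixtureDesign | None = None,
) -> InteractionResult:
    """Welch-corrected unpaired t comparison of experimental vs additive ED50.

    ``t = |ED50_add - ED50_exp| / sqrt(sem_add^2 + sem_exp^2)`` with
    Welch-Satterthwaite degrees of freedom built from the two SEMs with
    ``n_exp - 1`` and ``n_add - 1`` denominators; two-sided p.  Synergy is a
    significant reduction below the additive reference, antagonism a
    significant excess; otherwise additivity.
    """
    ref = additive.reference_ed50
    sem_add = additive.reference_sem
    if sem_exp <= 0 or sem_add is None or sem_add <= 0 or not math.isfinite(sem_add):
        raise ValueError("both SEMs must be positive and finite")
    if n_exp < 2 or additive.n_add < 2:
        raise ValueError("need n_exp >= 2 and n_add >= 2")
    se2 = sem_add**2 + sem_exp**2
    t = abs(ref - ed50_exp) / math.sqrt(se2)
    df = se2**2 / (
        sem_exp**4 / (n_exp - 1) + sem_add**4 / (additive.n_add - 1)
    )
    p = 2.0 * stats.t.sf(t, df)
    if p < alpha:
        label = "synergy" if ed50_exp < ref else "antagonism"
    else:
        label = "additivity"
    return InteractionResult(
        design=design,
        ed50_exp=ed50_exp,
        sem_exp=sem_exp,
        n_exp=n_exp,
        additive=additive,
        t_statistic=t,
        df=df,
        p_value=p,
        interaction_index=interaction_index(ed50_exp, additive),
        classification=label,
    )


def compromise_power(
    ed50_exp: float,
    sem_exp: float,
    n_exp: int,
    ed50_add: float,
    sem_add: float,
    n_add: int,
    q: float = 1.0,
) -> PowerReport:
    """Compromise power analysis for the two-sample comparison.

    Group SDs are reconstructed as ``SD_i = sem_i * sqrt(n_i)``; the effect
    size is Cohen's d with the pooled SD.  The critical t is chosen so that
    ``beta / alpha = q`` for the two-sided test with ``n_exp + n_add - 2``
    degrees of freedom and noncentrality ``d * sqrt(n_exp*n_add/(n_exp+n_add))``;
    the implied significance level and power ``1 - beta = 1 - q*alpha`` are
    returned.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    if sem_exp <= 0 or sem_add <= 0:
        raise ValueError("SEMs must be positive")
    if n_exp < 2 or n_add < 2:
        raise ValueError("need at least 2 per group")
    sd_exp = sem_exp * math.sqrt(n_exp)
    sd_add = sem_add * math.sqrt(n_add)
    pooled = math.sqrt(
        ((n_exp - 1) * sd_exp**2 + (n_add - 1) * sd_add**2) / (n_exp + n_add - 2)
    )
    d = abs(ed50_add - ed50_exp) / pooled
    return _compromise_from_effect(d, n_exp, n_add, q)


def _nct_interval(tc: float, df: float, ncp: float) -> float:
    """P(-tc < T' <= tc) for noncentral t, robust to scipy tail NaNs.

    scipy's boost-backed ``nct.cdf`` can return NaN deep in the lower tail
    for large noncentrality; fall back to the chi-mixture representation
    ``E_chi[Phi(tc*chi/sqrt(df) - ncp) - Phi(-tc*chi/sqrt(df) - ncp)]``.
    """
    lo = stats.nct.cdf(-tc, df, ncp)
    hi = stats.nct.cdf(tc, df, ncp)
    if math.isfinite(lo) and math.isfinite(hi):
        return hi - lo
    from scipy import integrate

    chi = stats.chi(df)
    s = math.sqrt(df)

    def integrand(c: float) -> float:
        return (
            stats.norm.cdf(tc * c / s - ncp) - stats.norm.cdf(-tc * c / s - ncp)
        ) * chi.pdf(c)

    val, _ = integrate.quad(integrand, 0.0, np.inf)
    return float(val)


def _compromise_from_effect(d: float, n1: int, n2: int, q: float) -> PowerReport:
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))

    def balance(tc: float) -> float:
        alpha = 2.0 * stats.t.sf(tc, df)
        beta = _nct_interval(tc, df, ncp)
        return beta - q * alpha

    lo, hi = 1e-9, 1.0
    while balance(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ArithmeticError(
                f"no compromise critical value found (d={d}, q={q}, df={df})"
            )
    tc = optimize.brentq(balance, lo, hi, rtol=1e-12)
    alpha = 2.0 * stats.t.sf(tc, df)
    beta = _nct_interval(tc, df, ncp)
    if not 0.0 < alpha < 1.0:
        raise ArithmeticError("implied alpha outside (0, 1)")
    return PowerReport(
        effect_size_d=d,
        implied_alpha=alpha,
        implied_power=1.0 - beta,
        beta_alpha_ratio_q=q,
        df=df,
        critical_t=tc,
    )


def therapeutic_index(td50: float, ed50: float) -> float:
    """TI = TD50 / ED50 (median toxic over median effective dose)."""
    if ed50 <= 0:
        raise ValueError("ed50 must be positive")
    if td50 <= 0:
        raise ValueError("td50 must be positive")
    return td50 / ed50


def mixture_component_doses(
    design: MixtureDesign, total_dose: float
) -> tuple[float, float]:
    """Split a total mixture dose into its component doses along the ray.

    At ``total_dose == design.additive_total`` each component equals
    ``f`` (resp. ``1-f``) times its own ED50.
    """
    if total_dose < 0:
        raise ValueError("total_dose must be non-negative")
    w = design.weight_a
    return total_dose * w, total_dose * (1.0 - w)
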