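"""Log-dose probit regression for quantal assays, Litchfield–Wilcoxon style.

The model: the probability that an animal is protected at dose ``d`` follows
``p(d) = Phi(b * (log10 d - log10 ED50))``, equivalently a straight line in
(log10 dose, probit) space, ``probit(p) = a + b log10 d``, where the probit
carries the classical +5 offset so the median effect sits at 5 probits and
the 16%/84% effects at 4 and 6 probits.  The ED50 is the dose whose fitted
probit equals 5.

Estimation is unweighted least squares on the per-group adjusted probit
points, the workflow of classical nomographic probit analysis; an optional
maximum-likelihood binomial-probit fit is available as a cross-check and its
ED50 is always recorded in the diagnostics.

The Litchfield–Wilcoxon slope function ``S = (ED84/ED50 + ED50/ED16)/2``
collapses to ``10**(1/b)`` on a straight probit line and feeds the
parallelism test: two lines are declared non-parallel when their slope-
function ratio S.R. exceeds the combined factor f S.R. built from the
per-line factors ``f_S = S**(2.77/sqrt(n))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .data import DoseResponseDataset

__all__ = [
    "PROBIT_OFFSET",
    "probit_transform",
    "inverse_probit",
    "adjust_extreme_proportion",
    "LogProbitRegression",
    "ProbitFit",
    "ParallelismResult",
    "fit_log_probit",
    "slope_function",
    "test_parallelism",
]

#: Classical probit offset: probit(p) = Phi^{-1}(p) + 5.
PROBIT_OFFSET = 5.0

#: Exponent constant of the Litchfield–Wilcoxon slope-function factor,
#: f_S = S ** (2.77 / sqrt(n)).
LW_FACTOR_CONSTANT = 2.77

#: Effect window (16%..84%, i.e. 4..6 probits) defining the animals that
#: contribute dose-response information.
EFFECT_WINDOW = (0.16, 0.84)


def probit_transform(p: float | np.ndarray) -> float | np.ndarray:
    """Map a proportion in (0, 1) to probit units (offset +5).

    Raises ``ValueError`` for p outside the open interval; callers holding
    0%/100% groups should first apply :func:`adjust_extreme_proportion`.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0.0) | (arr >= 1.0)):
        raise ValueError(
            "proportion must lie strictly in (0, 1); use "
            "adjust_extreme_proportion for all-or-none groups"
        )
    out = stats.norm.ppf(arr) + PROBIT_OFFSET
    return float(out) if np.isscalar(p) else out


def inverse_probit(y: float | np.ndarray) -> float | np.ndarray:
    """Map probit units back to a proportion."""
    out = stats.norm.cdf(np.asarray(y, dtype=float) - PROBIT_OFFSET)
    return float(out) if np.isscalar(y) else out


def adjust_extreme_proportion(
    n_protected: int, n_total: int, correction: float = 0.25
) -> float:
    """Observed proportion with all-or-none groups pulled off the boundary.

    0/n maps to ``correction/n`` and n/n to ``(n - correction)/n`` so the
    probit transform stays finite; interior proportions pass through
    unchanged.  ``correction`` defaults to the 0.25-animal convention.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_protected <= n_total:
        raise ValueError("n_protected must be in [0, n_total]")
    if n_protected == 0:
        return correction / n_total
    if n_protected == n_total:
        return (n_total - correction) / n_total
    return n_protected / n_total


@dataclass(frozen=True)
class ProbitFit:
    """A fitted log-probit line and the quantities derived from it.

    All dose-scale quantities are mg/kg.  ``slope_function_S`` is the
    Litchfield–Wilcoxon S; ``n_effective`` counts animals in groups whose
    *fitted* effect lies within 16–84%; ``n_used_total`` counts all animals
    in the dataset.
    """

    agent_id: str
    intercept_a: float
    slope_b: float
    ed50: float
    log10_ed50: float
    sem_ed50: float
    ci95: tuple[float, float]
    slope_function_S: float
    n_effective: int
    n_used_total: int
    fit_diagnostics: dict = field(default_factory=dict, compare=False)

    @property
    def se_log10_ed50(self) -> float:
        """Standard error on the log10 dose scale (delta-method inverse)."""
        return self.sem_ed50 / (self.ed50 * math.log(10.0))

    def predict_proportion(self, dose: float | np.ndarray) -> float | np.ndarray:
        z = self.intercept_a + self.slope_b * np.log10(dose) - PROBIT_OFFSET
        out = stats.norm.cdf(z)
        return float(out) if np.isscalar(dose) else out

    def ed(self, effect: float) -> float:
        """Dose producing the given effect proportion (e.g. 0.16, 0.84)."""
        target = probit_transform(effect)
        return 10.0 ** ((target - self.intercept_a) / self.slope_b)


@dataclass(frozen=True)
class ParallelismResult:
    """Litchfield–Wilcoxon parallelism verdict for two fitted lines."""

    agent_a: str
    agent_b: str
    slope_ratio_SR: float
    factor_fSR: float
    parallel: bool


class LogProbitRegression(BaseEstimator):
    """Quantal log-probit regression with ED50 and LW slope-function output.

    Parameters
    ----------
    correction : float, default 0.25
        Animals' worth of probability used to pull 0%/100% groups off the
        boundary before the probit transform.
    se_method : {"binomial", "residual"}, default "binomial"
        How the covariance of the fitted line (hence the ED50 standard
        error) is computed.  ``"binomial"`` uses a sandwich form with the
        known binomial variance of each group probit evaluated on the fitted
        curve; ``"residual"`` uses the ordinary residual-based OLS covariance
        (undefined with only two dose levels).
    ml_crosscheck : bool, default True
        Also run a maximum-likelihood binomial probit fit and record its
        ED50 (and the LS-vs-ML discrepancy) in ``fit_diagnostics``.

    Attributes (after ``fit``)
    --------------------------
    intercept_, slope_ : float
        Line coefficients in probit = intercept_ + slope_ * log10(dose).
    ed50_, log10_ed50_, sem_ed50_, ci95_ : fitted ED50 and its error.
    slope_function_ : float
        LW slope function S = 10**(1/slope_).
    n_effective_, n_used_total_ : int
    result_ : ProbitFit
        Immutable record of the full fit.

    Examples
    --------
    >>> reg = LogProbitRegression()
    >>> reg.fit([10.0, 40.0], [2, 6], n_total=8)
    LogProbitRegression()
    >>> round(reg.ed50_, 6)
    20.0
    """

    def __init__(
        self,
        correction: float = 0.25,
        se_method: Literal["binomial", "residual"] = "binomial",
        ml_crosscheck: bool = True,
    ):
        self.correction = correction
        self.se_method = se_method
        self.ml_crosscheck = ml_crosscheck

    # -- sklearn plumbing ---------------------------------------------------

    def _validate_counts(self, X, y, n_total):
        doses = np.asarray(X, dtype=float).reshape(-1)
        k = np.asarray(y, dtype=float).reshape(-1)
        if n_total is None:
            raise ValueError("n_total (animals per group) is required")
        n = np.broadcast_to(np.asarray(n_total, dtype=float), k.shape).copy()
        if doses.shape != k.shape:
            raise ValueError("X and y must have the same length")
        if np.any(doses <= 0):
            raise ValueError("doses must be positive")
        if np.any((k < 0) | (k > n)) or np.any(n < 1):
            raise ValueError("need 0 <= n_protected <= n_total and n_total >= 1")
        return doses, k, n

    def fit(self, X, y, n_total=None, agent_id: str = ""):
        """Fit on doses ``X`` (mg/kg) and protected counts ``y`` of ``n_total``.

        ``X`` may be 1-D or a column vector.  Duplicate-dose groups are
        pooled before the transform.
        """
        doses, k, n = self._validate_counts(X, y, n_total)
        # pool duplicate dose levels
        order: dict[float, list[float]] = {}
        for d, ki, ni in zip(doses, k, n):
            a = order.setdefault(float(d), [0.0, 0.0])
            a[0] += ki
            a[1] += ni
        dose_levels = np.array(sorted(order))
        if dose_levels.size < 2:
            raise ValueError("need >= 2 distinct dose levels")
        kk = np.array([order[d][0] for d in dose_levels])
        nn = np.array([order[d][1] for d in dose_levels])

        p_adj = np.array(
            [
                adjust_extreme_proportion(int(ki), int(ni), self.correction)
                for ki, ni in zip(kk, nn)
            ]
        )
        if np.allclose(p_adj, p_adj[0]):
            raise ValueError("all adjusted responses identical; cannot fit a line")

        x = np.log10(dose_levels)
        yprob = probit_transform(p_adj)
        X_design = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X_design, yprob, rcond=None)
        a, b = float(beta[0]), float(beta[1])

        diagnostics: dict = {"dose_levels": dose_levels.tolist()}
        if b <= 0:
            diagnostics["nonpositive_slope"] = True

        log10_ed50 = (PROBIT_OFFSET - a) / b
        # exponent clipping only matters for pathological near-flat fits,
        # which are flagged in diagnostics rather than raised
        ed50 = float(10.0 ** np.clip(log10_ed50, -300.0, 300.0))

        cov = self._line_covariance(X_design, x, yprob, a, b, nn, diagnostics)
        grad = np.array([-1.0 / b, -log10_ed50 / b])
        var_log = float(grad @ cov @ grad)
        se_log = math.sqrt(max(var_log, 0.0))
        sem_ed50 = ed50 * math.log(10.0) * se_log
        half = float(np.clip(1.96 * se_log, 0.0, 300.0))
        ci95 = (ed50 * 10.0**-half, ed50 * 10.0**half)

        fitted_p = stats.norm.cdf(a + b * x - PROBIT_OFFSET)
        lo, hi = EFFECT_WINDOW
        in_window = (fitted_p >= lo) & (fitted_p <= hi)
        n_effective = int(nn[in_window].sum())

        resid = yprob - (a + b * x)
        diagnostics["per_group_residuals"] = resid.tolist()
        diagnostics["sse"] = float(resid @ resid)
        # Pearson chi-square against fitted proportions (goodness of fit)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = float(
                np.sum((kk - nn * fitted_p) ** 2 / (nn * fitted_p * (1 - fitted_p)))
            )
        diagnostics["pearson_chi2"] = chi2
        diagnostics["curve_fitting_parameters"] = {"q": a, "p": b}

        if self.ml_crosscheck and b > 0:
            ml = self._ml_fit(x, kk, nn, a, b)
            if ml is not None:
                diagnostics["ml_ed50"] = ml
                diagnostics["ls_vs_ml_ed50_rel_diff"] = (ed50 - ml) / ml

        self.intercept_ = a
        self.slope_ = b
        self.ed50_ = ed50
        self.log10_ed50_ = log10_ed50
        self.sem_ed50_ = sem_ed50
        self.ci95_ = ci95
        self.slope_function_ = 10.0 ** (1.0 / b) if b > 0 else float("nan")
        self.n_effective_ = n_effective
        self.n_used_total_ = int(nn.sum())
        self.result_ = ProbitFit(
            agent_id=agent_id,
            intercept_a=a,
            slope_b=b,
            ed50=ed50,
            log10_ed50=log10_ed50,
            sem_ed50=sem_ed50,
            ci95=ci95,
            slope_function_S=self.slope_function_,
            n_effective=n_effective,
            n_used_total=self.n_used_total_,
            fit_diagnostics=diagnostics,
        )
        return self

    def _line_covariance(self, X_design, x, yprob, a, b, nn, diagnostics):
        XtX_inv = np.linalg.inv(X_design.T @ X_design)
        if self.se_method == "residual":
            dof = x.size - 2
            if dof < 1:
                diagnostics["se_warning"] = (
                    "residual covariance undefined with 2 dose levels"
                )
                return np.full((2, 2), np.nan)
            resid = yprob - X_design @ np.array([a, b])
            s2 = float(resid @ resid) / dof
            return s2 * XtX_inv
        # binomial: delta-method variance of each group probit on the fitted
        # curve, sandwiched through the unweighted projection
        z = a + b * x - PROBIT_OFFSET
        p_fit = np.clip(stats.norm.cdf(z), 1e-9, 1 - 1e-9)
        phi = stats.norm.pdf(z)
        v = p_fit * (1.0 - p_fit) / (nn * phi**2)
        meat = X_design.T @ (X_design * v[:, None])
        return XtX_inv @ meat @ XtX_inv

    @staticmethod
    def _ml_fit(x, kk, nn, a0, b0):
        def negll(theta):
            a, b = theta
            p = np.clip(stats.norm.cdf(a + b * x - PROBIT_OFFSET), 1e-12, 1 - 1e-12)
            return -float(np.sum(kk * np.log(p) + (nn - kk) * np.log(1 - p)))

        res = optimize.minimize(negll, [a0, b0], method="Nelder-Mead")
        if not res.success or res.x[1] <= 0:
            return None
        return float(10.0 ** ((PROBIT_OFFSET - res.x[0]) / res.x[1]))

    def predict(self, X):
        """Predicted protected proportion at doses ``X``."""
        doses = np.asarray(X, dtype=float).reshape(-1)
        return self.result_.predict_proportion(doses)


# -- module-level wrappers following the classical workflow ------------------


def fit_log_probit(
    data: DoseResponseDataset,
    correction: float = 0.25,
    se_method: Literal["binomial", "residual"] = "binomial",
    ml_crosscheck: bool = True,
) -> ProbitFit:
    """Fit a log10-dose probit line to a quantal dataset and derive the ED50."""
    pooled = data.pooled()
    doses = [g.dose for g in pooled.groups]
    k = [g.n_protected for g in pooled.groups]
    n = [g.n_total for g in pooled.groups]
    reg = LogProbitRegression(
        correction=correction, se_method=se_method, ml_crosscheck=ml_crosscheck
    )
    reg.fit(doses, k, n_total=n, agent_id=data.agent_id)
    return reg.result_


def slope_function(fit: ProbitFit | float) -> float:
    """Litchfield–Wilcoxon slope function S of a fitted line.

    ``S = (ED84/ED50 + ED50/ED16)/2``; on a straight probit line both dose
    ratios equal ``10**(1/b)`` so the mean collapses to that value.  Accepts
    a :class:`ProbitFit` or a raw positive slope.
    """
    b = fit.slope_b if isinstance(fit, ProbitFit) else float(fit)
    if not b > 0:
        raise ValueError("slope must be positive to define the slope function")
    return 10.0 ** (1.0 / b)


def estimable(fit: ProbitFit, doses, bracket_factor: float = 4.0) -> bool:
    """Assay-validity screen for a fitted line.

    A quantal design is informative about the ED50 only when the tested
    doses bracket it; a non-positive fitted slope or an ED50 far outside
    the tested range (beyond ``bracket_factor`` times the bracket) marks a
    failed replicate that would be re-dosed in practice rather than
    reported.
    """
    doses = np.asarray(doses, dtype=float)
    if fit.slope_b <= 0:
        return False
    return doses.min() / bracket_factor <= fit.ed50 <= doses.max() * bracket_factor


def _slope_factor(S: float, n_effective: int) -> float:
    return S ** (LW_FACTOR_CONSTANT / math.sqrt(n_effective))


def test_parallelism(fit_a: ProbitFit, fit_b: ProbitFit) -> ParallelismResult:
    """LW test of parallelism of two fitted log-probit lines.

    S.R. is the larger-over-smaller slope-function ratio; the critical factor
    f S.R. combines the per-line factors ``f_Si = S_i**(2.77/sqrt(n_i))`` as
    ``antilog sqrt(log(f_Sa)**2 + log(f_Sb)**2)``.  The lines are parallel
    when S.R. <= f S.R.
    """
    for f in (fit_a, fit_b):
        if f.n_effective <= 0:
            raise ValueError(
                f"fit {f.agent_id!r} has no animals in the 16-84% effect window"
            )
    S_a = slope_function(fit_a)
    S_b = slope_function(fit_b)
    sr = max(S_a, S_b) / min(S_a, S_b)
    f_a = _slope_factor(S_a, fit_a.n_effective)
    f_b = _slope_factor(S_b, fit_b.n_effective)
    fsr = 10.0 ** math.sqrt(math.log10(f_a) ** 2 + math.log10(f_b) ** 2)
    return ParallelismResult(
        agent_a=fit_a.agent_id,
        agent_b=fit_b.agent_id,
        slope_ratio_SR=sr,
        factor_fSR=fsr,
        parallel=sr <= fsr,
    )


# the name starts with "test_" but this is library API, not a test case
test_parallelism.__test__ = False  # type: ignore[attr-defined]
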