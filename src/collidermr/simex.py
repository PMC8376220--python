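"""Simulation-extrapolation (SIMEX) adjustment for weak-instrument dilution.

Because the collider-corrected residuals are independent of the first-stage
estimation errors, uncertainty in beta_XG_hat acts on the slope fit exactly
like classical measurement error in the regressor.  SIMEX exploits this: a
parametric bootstrap adds *extra* first-stage noise at multiples lambda of
the observed variance (pseudo associations beta_XG_hat + sqrt(lambda) *
se_XG * Z), the estimator is re-run on each pseudo summary, a global model
(quadratic in lambda by default) is fitted to the per-lambda mean slopes,
and the curve is extrapolated back to lambda = -1 — the estimate that would
have been obtained with no first-stage uncertainty at all (NOME satisfied).

Variance estimation follows the standard difference method: the sampling
variance component mean_b[se^2(lambda, b)] - Var_b[slope(lambda, b)] is
extrapolated to lambda = -1 alongside the point estimate.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, NumericalError
from .estimators import SLOPE_ESTIMATORS, SlopeEstimate

logger = logging.getLogger("collidermr")

__all__ = ["SimexConfig", "simex_adjust"]


@dataclass(frozen=True)
class SimexConfig:
    """SIMEX tuning parameters.

    ``lambdas`` must start at 0 (the anchor, evaluated on the observed
    summary without resampling) and increase strictly; ``b`` pseudo
    summaries are drawn per positive lambda.
    """

    lambdas: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    b: int = 100
    extrapolant: str = "quadratic"
    seed: int | None = None
    jackknife_se: bool = True

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if len(lam) < 2 or lam[0] != 0.0 or np.any(np.diff(lam) <= 0):
            raise ConfigError("lambdas must start at 0 and increase strictly")
        if self.extrapolant == "quadratic" and len(lam) < 3:
            raise ConfigError("quadratic extrapolation needs at least 3 lambdas")
        if self.b < 2:
            raise ConfigError("b must be >= 2")
        if self.extrapolant not in ("quadratic", "linear"):
            raise ConfigError(f"unknown extrapolant {self.extrapolant!r}")


def _extrapolate(lam: np.ndarray, values: np.ndarray, degree: int) -> float:
    coef = np.polyfit(lam, values, deg=degree)
    return float(np.polyval(coef, -1.0))


def simex_adjust(estimator, summary, config: SimexConfig | None = None, **estimator_kwargs) -> SlopeEstimate:
    """SIMEX-adjust any slope estimator consuming a first-stage summary.

    ``estimator`` is a name from :data:`collidermr.estimators.SLOPE_ESTIMATORS`
    ('ivw', 'egger', 'lad', ...) or any callable mapping a summary object —
    anything with ``beta_xg``/``se_xg`` fields, e.g. a
    :class:`~collidermr.regress.ColliderSummary` or
    :class:`~collidermr.regress.TwoSampleSummary` — to a
    :class:`SlopeEstimate`.  If all first-stage SEs are zero the pseudo data
    are identical and the unadjusted estimate is returned.
    """
    if config is None:
        config = SimexConfig()
    if isinstance(estimator, str):
        if estimator == "standard-ivw":
            from .estimators import standard_ivw_slope as est_fun
        elif estimator in SLOPE_ESTIMATORS:
            est_fun = SLOPE_ESTIMATORS[estimator]
        else:
            raise ConfigError(f"unknown estimator {estimator!r}")
    else:
        est_fun = estimator

    rng = np.random.default_rng(config.seed)
    lam = np.asarray(config.lambdas, dtype=float)
    degree = 2 if config.extrapolant == "quadratic" else 1

    base = est_fun(summary, **estimator_kwargs)
    se_xg = np.asarray(summary.se_xg, dtype=float)
    k = len(se_xg)

    mean_slope = [base.slope]
    var_comp = [base.se_slope**2]
    mean_intercept = [base.intercept] if base.intercept is not None else None

    for lam_i in lam[1:]:
        slopes = np.full(config.b, np.nan)
        ses = np.full(config.b, np.nan)
        icepts = np.full(config.b, np.nan)
        n_fail = 0
        for b in range(config.b):
            pseudo_beta = summary.beta_xg + np.sqrt(lam_i) * se_xg * rng.standard_normal(k)
            pseudo = dataclasses.replace(summary, beta_xg=pseudo_beta)
            try:
                est = est_fun(pseudo, **estimator_kwargs)
            except Exception as exc:  # single-pseudo failures are tolerated
                n_fail += 1
                logger.warning("SIMEX pseudo-fit failed at lambda=%g: %s", lam_i, exc)
                continue
            slopes[b] = est.slope
            ses[b] = est.se_slope
            if est.intercept is not None:
                icepts[b] = est.intercept
        if n_fail > config.b // 2:
            raise NumericalError(
                f"estimator failed on {n_fail}/{config.b} pseudo-datasets at lambda={lam_i}"
            )
        ok = np.isfinite(slopes)
        mean_slope.append(float(np.mean(slopes[ok])))
        ses_ok = ses[ok]
        if np.isfinite(ses_ok).all():
            var_comp.append(float(np.mean(ses_ok**2) - np.var(slopes[ok], ddof=1)))
        else:
            var_comp.append(np.nan)
        if mean_intercept is not None:
            mean_intercept.append(float(np.nanmean(icepts)))

    slope_adj = _extrapolate(lam, np.asarray(mean_slope), degree)
    icept_adj = (
        _extrapolate(lam, np.asarray(mean_intercept), degree)
        if mean_intercept is not None
        else None
    )

    se_adj = base.se_slope
    if config.jackknife_se and np.isfinite(var_comp).all():
        var_extrap = _extrapolate(lam, np.asarray(var_comp), degree)
        if var_extrap > 0:
            se_adj = float(np.sqrt(var_extrap))
        else:
            logger.warning("SIMEX variance extrapolation non-positive; keeping base SE")

    return SlopeEstimate(
        method=f"{base.method}+simex",
        slope=slope_adj,
        se_slope=se_adj,
        intercept=icept_adj,
        phi=base.phi,
        converged=base.converged,
        extras={
            "lambdas": lam.tolist(),
            "mean_slopes": list(mean_slope),
            "variance_components": list(var_comp),
            "extrapolant": config.extrapolant,
            "unadjusted": base.slope,
            "estimand": base.extras.get("estimand", "slope"),
        },
    )
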