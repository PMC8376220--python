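"""Step 3 (slope estimation) and step 4 (add-back) of Collider-Correction.

Every estimator here fits the summary-level model

    alpha*_j_hat = alpha_0 + (beta - beta*) * beta_XGj_hat + error

under its own loss and pleiotropy-identifying assumption:

* :func:`ivw_slope`       weighted least squares through the origin
                          (alpha_0 = 0), multiplicative random effects.
* :func:`egger_slope`     weighted least squares with a free intercept
                          (directional pleiotropy under InSIDE).
* :func:`lad_slope`       weighted least-absolute-deviation through the
                          origin; robust to a minority of InSIDE-violating
                          SNPs (median-like breakdown).
* :func:`liml_raps_slope` profile estimation with exact first-stage-error
                          weighting: z=0 reproduces summary-data LIML, z=1 a
                          RAPS-style fit with Tukey-biweight penalization
                          and a profiled pleiotropy variance.

The causal effect is recovered by adding the fitted slope back onto the
conditional observational coefficient (:func:`causal_estimate`);
:func:`tsls` is the classic individual-level comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import integrate, optimize, stats
from statsmodels.sandbox.regression.gmm import IV2SLS

from .datagen import IndividualData
from .errors import ConfigError, DataError, NumericalError
from .regress import ColliderSummary, TwoSampleSummary, collider_summary

logger = logging.getLogger("collidermr")

__all__ = [
    "SlopeEstimate",
    "CausalEstimate",
    "ivw_slope",
    "standard_ivw_slope",
    "egger_slope",
    "lad_slope",
    "liml_raps_slope",
    "tsls",
    "causal_estimate",
    "SLOPE_ESTIMATORS",
]


@dataclass
class SlopeEstimate:
    """An estimate of the collider-correction slope (beta - beta*).

    ``phi`` is the multiplicative overdispersion scale, floored at 1; the
    raw value is kept in ``extras['phi_raw']``.  For the 'standard'
    comparator arms the slope is an estimate of beta itself
    (``extras['estimand'] == 'beta'``).
    """

    method: str
    slope: float
    se_slope: float
    intercept: float | None = None
    phi: float = 1.0
    converged: bool = True
    extras: dict = field(default_factory=dict)


@dataclass
class CausalEstimate:
    """The recovered causal effect beta_hat = beta*_hat + slope_hat."""

    beta_hat: float
    se: float
    p_value: float
    method: str
    components: dict | None = None


def _check_summary(x, se_y, k_min: int) -> None:
    if len(x) < k_min:
        raise ConfigError(f"need at least {k_min} SNPs, got {len(x)}")
    if np.any(np.asarray(se_y) <= 0):
        raise DataError("standard errors must be strictly positive")


def _wls_origin(x, y, w):
    sxx = float(np.sum(w * x * x))
    if sxx == 0:
        raise NumericalError("all SNP-exposure associations are zero")
    slope = float(np.sum(w * x * y) / sxx)
    return slope, 1.0 / sxx


def ivw_slope(summary: ColliderSummary, random_effects: bool = True) -> SlopeEstimate:
    """Collider-corrected IVW: WLS of alpha*_hat on beta_XG_hat through the origin.

    Weights are 1/se_alpha_star^2.  Under multiplicative random effects the
    SE is scaled by sqrt(phi) with phi = max(1, RSS_w / (k - 1)), absorbing
    balanced pleiotropy as overdispersion.
    """
    x, y = np.asarray(summary.beta_xg), np.asarray(summary.alpha_star)
    se_y = np.asarray(summary.se_alpha_star)
    _check_summary(x, se_y, 2)
    w = 1.0 / se_y**2
    slope, var = _wls_origin(x, y, w)
    resid = y - slope * x
    phi_raw = float(np.sum(w * resid**2) / (len(x) - 1))
    phi = max(1.0, phi_raw)
    se = float(np.sqrt(var * (phi if random_effects else 1.0)))
    return SlopeEstimate(
        method="ivw", slope=slope, se_slope=se, phi=phi,
        extras={"phi_raw": phi_raw, "random_effects": random_effects},
    )


def standard_ivw_slope(summary: TwoSampleSummary, random_effects: bool = True) -> SlopeEstimate:
    """'Standard' IVW on (beta_XG_hat, beta_YG_hat) pairs; estimates beta itself."""
    x, y = np.asarray(summary.beta_xg), np.asarray(summary.beta_yg)
    se_y = np.asarray(summary.se_yg)
    _check_summary(x, se_y, 2)
    w = 1.0 / se_y**2
    slope, var = _wls_origin(x, y, w)
    resid = y - slope * x
    phi_raw = float(np.sum(w * resid**2) / (len(x) - 1))
    phi = max(1.0, phi_raw)
    se = float(np.sqrt(var * (phi if random_effects else 1.0)))
    return SlopeEstimate(
        method="standard-ivw", slope=slope, se_slope=se, phi=phi,
        extras={"phi_raw": phi_raw, "estimand": "beta"},
    )


def egger_slope(summary: ColliderSummary) -> SlopeEstimate:
    """Collider-corrected MR-Egger: WLS with a freely estimated intercept.

    The intercept absorbs the mean pleiotropic effect; the slope remains
    consistent for (beta - beta*) under InSIDE even with directional
    pleiotropy.
    """
    x, y = np.asarray(summary.beta_xg), np.asarray(summary.alpha_star)
    se_y = np.asarray(summary.se_alpha_star)
    _check_summary(x, se_y, 3)
    if np.ptp(x) == 0:
        raise NumericalError("constant SNP-exposure associations: Egger slope unidentified")
    w = 1.0 / se_y**2
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    phi_raw = float(res.scale)  # = RSS_w / (k - 2) given unit-variance weights
    phi = max(1.0, phi_raw)
    bse_fixed = res.bse / np.sqrt(res.scale)
    se = float(bse_fixed[1] * np.sqrt(phi))
    return SlopeEstimate(
        method="egger",
        slope=float(res.params[1]),
        se_slope=se,
        intercept=float(res.params[0]),
        phi=phi,
        extras={"phi_raw": phi_raw, "se_intercept": float(bse_fixed[0] * np.sqrt(phi))},
    )


def _lad_point(x: np.ndarray, y: np.ndarray, se_y: np.ndarray) -> float:
    """Exact minimizer of sum_j |y_j - s x_j| / se_j over s.

    The objective is piecewise-linear and convex in s, so a minimizer lies
    at one of the data ratios y_j / x_j (a weighted median of ratios with
    weights |x_j| / se_j); ties are broken toward the smallest |s|.
    """
    w = 1.0 / se_y
    nz = x != 0
    if not nz.any():
        raise NumericalError("all SNP-exposure associations are zero")
    cand = np.concatenate([y[nz] / x[nz], [0.0]])
    loss = np.abs(y[None, :] - cand[:, None] * x[None, :]) @ w
    best = loss.min()
    ok = loss <= best * (1 + 1e-12) + 1e-300
    return float(cand[ok][np.argmin(np.abs(cand[ok]))])


def lad_slope(summary: ColliderSummary, n_boot: int = 1000, seed=None) -> SlopeEstimate:
    """Collider-corrected weighted LAD regression through the origin.

    Close in spirit to the weighted-median estimator but expressible as a
    regression, which is what makes SIMEX adjustment applicable to it.  The
    SE comes from a nonparametric bootstrap over SNPs (``n_boot`` draws,
    seeded); pass ``n_boot=0`` to skip it (SE reported as NaN).
    """
    x, y = np.asarray(summary.beta_xg), np.asarray(summary.alpha_star)
    se_y = np.asarray(summary.se_alpha_star)
    _check_summary(x, se_y, 2)
    slope = _lad_point(x, y, se_y)
    se = float("nan")
    if n_boot:
        rng = np.random.default_rng(seed)
        k = len(x)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, k, size=k)
            try:
                boots[b] = _lad_point(x[idx], y[idx], se_y[idx])
            except NumericalError:
                boots[b] = np.nan
        boots = boots[np.isfinite(boots)]
        if len(boots) < 2:
            raise NumericalError("bootstrap failed for LAD standard error")
        se = float(np.std(boots, ddof=1))
    return SlopeEstimate(method="lad", slope=slope, se_slope=se,
                         extras={"n_boot": n_boot})


# ---------------------------------------------------------------------------
# Exact-weighting profile estimators (LIML / RAPS-style) and the exact Q
# objective they share with the heterogeneity diagnostics.

def exact_q_objective(s: float, x, y, var_x, var_y, tau2: float = 0.0) -> float:
    """Weighted sum of squared residuals with exact first-stage weighting.

    Residual variance for SNP j at slope s is s^2 var_x_j + var_y_j + tau2,
    so weak instruments inflate rather than bias the fit.  At tau2 = 0 the
    minimum over s is the 'exact' Q statistic (chi-square, k-1 df, under no
    pleiotropy); the minimizer is the summary-data LIML slope.
    """
    denom = s * s * var_x + var_y + tau2
    return float(np.sum((y - s * x) ** 2 / denom))


def _minimize_profile(fun, center: float, half_width: float, n_starts: int = 5):
    """Multistart bounded 1-D minimization; returns (argmin, min, candidates)."""
    edges = np.linspace(center - half_width, center + half_width, n_starts + 1)
    cands: list[tuple[float, float]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        r = optimize.minimize_scalar(fun, bounds=(lo, hi), method="bounded",
                                     options={"xatol": 1e-10})
        cands.append((float(r.x), float(r.fun)))
    # dedupe near-identical solutions
    uniq: list[tuple[float, float]] = []
    for s, f in sorted(cands, key=lambda t: t[1]):
        if not any(abs(s - u) < 1e-6 * (1 + abs(s)) for u, _ in uniq):
            uniq.append((s, f))
    best_s, best_f = uniq[0]
    return best_s, best_f, uniq


def _tukey_rho(r, c):
    a = np.minimum(np.abs(r) / c, 1.0)
    return c**2 / 6.0 * (1.0 - (1.0 - a**2) ** 3)


def _tukey_psi(r, c):
    out = np.where(np.abs(r) <= c, r * (1.0 - (r / c) ** 2) ** 2, 0.0)
    return out


_TUKEY_DELTA_CACHE: dict[float, float] = {}


def _tukey_delta(c: float) -> float:
    """E[psi_c(R) * R] for R ~ N(0,1); calibrates the profiled tau^2."""
    if c not in _TUKEY_DELTA_CACHE:
        val, _ = integrate.quad(
            lambda r: _tukey_psi(r, c) * r * stats.norm.pdf(r), -c, c
        )
        _TUKEY_DELTA_CACHE[c] = val
    return _TUKEY_DELTA_CACHE[c]


def liml_raps_slope(
    summary: ColliderSummary,
    z: int = 0,
    penalization: str = "tukey",
    tukey_c: float = 4.685,
    n_starts: int = 5,
    bracket_sds: float = 10.0,
) -> SlopeEstimate:
    """Profile estimation of the slope with exact first-stage weighting.

    ``z=0`` fixes the pleiotropy variance tau^2 at zero and minimizes the
    exact-Q objective: summary-data LIML.  ``z=1`` additionally profiles
    tau^2 = Var(alpha*_j) and replaces the squared loss with a Tukey
    biweight, a RAPS-style fit that down-weights outlying SNPs; tau^2 is
    calibrated through the moment condition mean[psi(r) r] = E[psi(R) R]
    under standard-normal residuals, floored at zero.

    The slope search covers the interval IVW slope +/- ``bracket_sds`` IVW
    SEs.  For z=0 this is ``n_starts`` bounded minimizations with the global
    minimum returned; for z=1 the robust profile score is scanned for roots,
    every root is reported in ``extras['candidates']`` tagged stable or
    unstable, and the stable root closest to the IVW anchor is returned
    (``converged=False`` if none is stable — the instability the bounded
    loss is known for).
    """
    if z not in (0, 1):
        raise ConfigError(f"z must be 0 or 1, got {z}")
    if penalization not in ("tukey",):
        raise ConfigError(f"unsupported penalization {penalization!r}")
    x, y = np.asarray(summary.beta_xg), np.asarray(summary.alpha_star)
    var_x = np.asarray(summary.se_xg) ** 2
    var_y = np.asarray(summary.se_alpha_star) ** 2
    _check_summary(x, var_y, 2)

    anchor = ivw_slope(summary)
    half_width = max(bracket_sds * anchor.se_slope, 0.25)

    if z == 0:
        fun = lambda s: exact_q_objective(s, x, y, var_x, var_y)
        slope, q_min, cands = _minimize_profile(fun, anchor.slope, half_width, n_starts)
        interior = abs(slope - anchor.slope) < half_width * (1 - 1e-6)
        # curvature-based SE, treating Q as -2 log-likelihood profile
        h = max(1e-6, 1e-4 * abs(slope))
        d2 = (fun(slope + h) - 2 * q_min + fun(slope - h)) / h**2
        se = float(np.sqrt(2.0 / d2)) if d2 > 0 else float("nan")
        return SlopeEstimate(
            method="liml", slope=slope, se_slope=se, converged=bool(interior and d2 > 0),
            extras={"q_min": q_min, "candidates": cands},
        )

    c = tukey_c
    delta = _tukey_delta(c)

    def _profile_tau2(s: float) -> float:
        def moment(tau2):
            r = (y - s * x) / np.sqrt(s * s * var_x + var_y + tau2)
            return float(np.mean(_tukey_psi(r, c) * r)) - delta

        if moment(0.0) <= 0:
            return 0.0
        hi = float(np.max(var_y))
        for _ in range(60):
            if moment(hi) < 0:
                break
            hi *= 4.0
        else:
            raise NumericalError("tau^2 profile did not bracket")
        return float(optimize.brentq(lambda t: moment(t), 0.0, hi, xtol=1e-14))

    def score(s: float) -> float:
        # robust profile score for the slope at the profiled tau^2
        tau2 = _profile_tau2(s)
        den = s * s * var_x + var_y + tau2
        r = (y - s * x) / np.sqrt(den)
        d = (x * den + (y - s * x) * s * var_x) / den**1.5  # -d r / d s
        return float(np.sum(_tukey_psi(r, c) * d))

    # scan for score roots; a stable solution crosses zero from + to -
    # (the score is minus the gradient of the implied robust objective)
    grid = np.linspace(anchor.slope - half_width, anchor.slope + half_width,
                       max(8 * n_starts, 41))
    try:
        gvals = np.array([score(s) for s in grid])
        roots: list[tuple[float, bool]] = []
        for lo, hi, glo, ghi in zip(grid[:-1], grid[1:], gvals[:-1], gvals[1:]):
            if glo == 0.0:
                roots.append((float(lo), ghi < glo))
            elif glo * ghi < 0:
                root = float(optimize.brentq(score, lo, hi, xtol=1e-12))
                roots.append((root, glo > 0))
    except NumericalError:
        return SlopeEstimate(
            method="raps", slope=anchor.slope, se_slope=anchor.se_slope,
            converged=False, extras={"note": "tau^2 profile failure; IVW fallback"},
        )
    stable = [r for r, is_stable in roots if is_stable]
    if stable:
        slope = min(stable, key=lambda r: abs(r - anchor.slope))
        interior = True
    elif roots:
        slope = min((r for r, _ in roots), key=lambda r: abs(r - anchor.slope))
        interior = False
    else:
        slope = anchor.slope
        interior = False
    cands = [(r, "stable" if st else "unstable") for r, st in roots]
    tau2_hat = _profile_tau2(slope)

    # M-estimator sandwich SE with numerically differentiated residual map
    h = max(1e-6, 1e-4 * abs(slope))

    def _resid(s):
        return (y - s * x) / np.sqrt(s * s * var_x + var_y + tau2_hat)

    r0 = _resid(slope)
    dr = (_resid(slope + h) - _resid(slope - h)) / (2 * h)
    psi = _tukey_psi(r0, c)
    dpsi = (_tukey_psi(r0 + 1e-6, c) - _tukey_psi(r0 - 1e-6, c)) / 2e-6
    a_mat = float(np.sum(dpsi * dr * dr))
    b_mat = float(np.sum(psi**2 * dr**2))
    se = float(np.sqrt(b_mat) / abs(a_mat)) if a_mat != 0 else float("nan")
    return SlopeEstimate(
        method="raps", slope=slope, se_slope=se,
        converged=bool(interior and np.isfinite(se)),
        extras={"tau2": tau2_hat, "candidates": cands, "tukey_c": c},
    )


def tsls(data: IndividualData, covariates=None) -> CausalEstimate:
    """Two-stage least squares on the individual-level data (comparator arm).

    The exposure is regressed on all SNPs jointly; the outcome on the
    genetically predicted exposure, with the usual corrected second-stage
    SEs.  Weak instruments do not raise here — inspect the diagnostics.
    """
    g = np.asarray(data.genotypes, dtype=np.float64)
    x = np.asarray(data.exposure, dtype=np.float64)
    y = np.asarray(data.outcome, dtype=np.float64)
    n = len(x)
    ones = np.ones((n, 1))
    c = None
    if covariates is not None:
        c = np.asarray(covariates, dtype=np.float64)
        if c.ndim == 1:
            c = c[:, None]
    exog = np.hstack([ones, x[:, None]] + ([c] if c is not None else []))
    instr = np.hstack([ones, g] + ([c] if c is not None else []))
    res = IV2SLS(y, exog, instrument=instr).fit()
    beta = float(res.params[1])
    se = float(res.bse[1])
    p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    return CausalEstimate(beta_hat=beta, se=se, p_value=p, method="tsls")


def causal_estimate(
    slope_est: SlopeEstimate,
    summary: ColliderSummary,
    df: int | None = None,
) -> CausalEstimate:
    """Step 4: add the fitted slope back onto the observational coefficient.

    The default SE combines the two components as if independent,
    sqrt(se_beta_star^2 + se_slope^2); the p-value is two-sided normal
    unless ``df`` is given, in which case a t reference is used.
    """
    if slope_est.extras.get("estimand") == "beta":
        raise ConfigError(
            "standard-arm slope already estimates beta; do not add beta_star back"
        )
    beta_hat = summary.beta_star + slope_est.slope
    se = float(np.sqrt(summary.se_beta_star**2 + slope_est.se_slope**2))
    if se > 0 and np.isfinite(se):
        zval = abs(beta_hat) / se
        p = float(2 * (stats.t.sf(zval, df) if df else stats.norm.sf(zval)))
    else:
        p = float("nan")
    return CausalEstimate(
        beta_hat=beta_hat,
        se=se,
        p_value=p,
        method=slope_est.method,
        components={
            "beta_star": summary.beta_star,
            "se_beta_star": summary.se_beta_star,
            "slope": slope_est.slope,
            "se_slope": slope_est.se_slope,
        },
    )


def paired_bootstrap_causal(
    data: IndividualData,
    method: str = "ivw",
    n_boot: int = 200,
    seed=None,
    covariates=None,
) -> CausalEstimate:
    """Exact-covariance alternative to the independence SE combination.

    Resamples individuals, re-runs steps 1-4 with the requested estimator,
    and reports the bootstrap SD of the causal estimate.
    """
    if method not in SLOPE_ESTIMATORS:
        raise ConfigError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    point_summary = collider_summary(data, covariates=covariates)
    point = causal_estimate(_fit_method(method, point_summary), point_summary)
    n = data.n
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = IndividualData(
            genotypes=data.genotypes[idx],
            exposure=data.exposure[idx],
            outcome=data.outcome[idx],
            covariates=None if data.covariates is None else data.covariates[idx],
        )
        cov_b = None if covariates is None else np.asarray(covariates)[idx]
        s = collider_summary(boot, covariates=cov_b)
        vals[b] = causal_estimate(_fit_method(method, s), s).beta_hat
    se = float(np.std(vals, ddof=1))
    p = float(2 * stats.norm.sf(abs(point.beta_hat) / se)) if se > 0 else float("nan")
    return CausalEstimate(
        beta_hat=point.beta_hat, se=se, p_value=p,
        method=f"{method}+paired-bootstrap", components=point.components,
    )


def _fit_method(method: str, summary: ColliderSummary, **kwargs) -> SlopeEstimate:
    return SLOPE_ESTIMATORS[method](summary, **kwargs)


SLOPE_ESTIMATORS = {
    "ivw": ivw_slope,
    "egger": egger_slope,
    "lad": lad_slope,
    "liml": lambda s, **kw: liml_raps_slope(s, z=0, **kw),
    "raps": lambda s, **kw: liml_raps_slope(s, z=1, **kw),
}
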