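"""Weak-instrument and pleiotropy diagnostics for a collider summary.

Three statistics drive the interpretation of any Collider-Correction fit:

* the mean instrument-strength statistic F-bar, which predicts the IVW
  slope dilution factor (F-bar - 1)/F-bar under first-stage uncertainty;
* I2GX, the weighted heterogeneity of the first-stage estimates, which
  predicts the MR-Egger slope dilution factor directly;
* the 'exact' Q statistic — the minimized exact-weighting objective — which
  is chi-square with k-1 degrees of freedom when no SNP is pleiotropic and
  remains valid under weak instruments; its per-SNP components flag
  outliers at a Bonferroni-corrected chi-square(1) threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .estimators import _minimize_profile, exact_q_objective, ivw_slope
from .regress import ColliderSummary

logger = logging.getLogger("collidermr")

__all__ = [
    "DiagnosticReport",
    "QResult",
    "mean_f",
    "sum_f",
    "isq_gx",
    "exact_q",
    "flag_outliers",
    "predicted_dilution",
    "diagnostic_report",
]


@dataclass
class QResult:
    """Exact Q statistic, reference df/p-value and per-SNP contributions."""

    q: float
    df: int
    p: float
    per_snp: np.ndarray
    slope: float


@dataclass
class DiagnosticReport:
    mean_f: float
    i2gx: float
    q_exact: float
    q_df: int
    q_p: float
    per_snp_q: np.ndarray
    outliers: list
    dilution_ivw: float
    dilution_egger: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_f": self.mean_f,
            "i2gx": self.i2gx,
            "q_exact": self.q_exact,
            "q_df": self.q_df,
            "q_p": self.q_p,
            "outliers": list(self.outliers),
            "dilution_ivw": self.dilution_ivw,
            "dilution_egger": self.dilution_egger,
            "extras": {k: float(v) for k, v in self.extras.items()},
        }


def _first_stage(summary) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(summary.beta_xg, dtype=float)
    se = np.asarray(summary.se_xg, dtype=float)
    if np.any(se <= 0):
        raise DataError("first-stage standard errors must be positive")
    return b, se


def mean_f(summary) -> float:
    """Mean per-SNP F statistic, (1/k) sum_j beta_XGj^2 / se_XGj^2."""
    b, se = _first_stage(summary)
    return float(np.mean(b**2 / se**2))


def sum_f(summary) -> float:
    """Sum of the per-SNP F statistics (the bare-sum variant of F-bar)."""
    b, se = _first_stage(summary)
    return float(np.sum(b**2 / se**2))


def isq_gx(summary, weighted_mean: bool = True) -> float:
    """I2GX = (Q_GX - (k-1)) / Q_GX, floored at 0.

    Q_GX is the weighted heterogeneity of the first-stage estimates about
    their inverse-variance-weighted mean (unweighted mean with
    ``weighted_mean=False``).  Values near 0 signal severe regression
    dilution for MR-Egger; near 1, almost none.
    """
    b, se = _first_stage(summary)
    if len(b) < 2:
        raise ConfigError("I2GX needs at least 2 SNPs")
    w = 1.0 / se**2
    center = np.sum(w * b) / np.sum(w) if weighted_mean else np.mean(b)
    q_gx = float(np.sum((b - center) ** 2 * w))
    if q_gx == 0:
        return 0.0
    return float(max(0.0, (q_gx - (len(b) - 1)) / q_gx))


def exact_q(summary: ColliderSummary, slope: float | None = None) -> QResult:
    """Exact Q statistic; profile-minimized over the slope unless one is given.

    Shares its objective with the LIML estimator, whose point estimate is
    the minimizing slope.
    """
    x = np.asarray(summary.beta_xg)
    y = np.asarray(summary.alpha_star)
    var_x = np.asarray(summary.se_xg) ** 2
    var_y = np.asarray(summary.se_alpha_star) ** 2
    k = len(x)
    if k < 2:
        raise ConfigError("exact Q needs at least 2 SNPs")
    if slope is None:
        anchor = ivw_slope(summary)
        half_width = max(10.0 * anchor.se_slope, 0.25)
        slope, _, _ = _minimize_profile(
            lambda s: exact_q_objective(s, x, y, var_x, var_y),
            anchor.slope,
            half_width,
        )
    per_snp = (y - slope * x) ** 2 / (slope**2 * var_x + var_y)
    q = float(per_snp.sum())
    return QResult(q=q, df=k - 1, p=float(stats.chi2.sf(q, k - 1)), per_snp=per_snp,
                   slope=float(slope))


def flag_outliers(per_snp_q: np.ndarray, k: int | None = None, level: float = 0.05,
                  snp_ids=None) -> list:
    """SNPs whose Q contribution exceeds the Bonferroni chi-square(1) cutoff."""
    per_snp_q = np.asarray(per_snp_q)
    if k is None:
        k = len(per_snp_q)
    cutoff = stats.chi2.ppf(1.0 - level / k, 1)
    idx = np.flatnonzero(per_snp_q > cutoff)
    if snp_ids is None:
        return idx.tolist()
    return [snp_ids[i] for i in idx]


def predicted_dilution(summary, method: str = "ivw") -> float:
    """Predicted multiplicative slope dilution for the chosen estimator.

    (F-bar - 1)/F-bar for IVW (and approximately for LAD, which is somewhat
    more dilution-prone); I2GX for MR-Egger.  Returns 0 with a warning when
    F-bar < 1.
    """
    if method in ("ivw", "lad"):
        f = mean_f(summary)
        if f < 1.0:
            logger.warning("mean F = %.3f < 1; dilution factor floored at 0", f)
            return 0.0
        return float((f - 1.0) / f)
    if method == "egger":
        return isq_gx(summary)
    raise ConfigError(f"no dilution prediction for method {method!r}")


def diagnostic_report(summary: ColliderSummary, level: float = 0.05) -> DiagnosticReport:
    """Compute the full diagnostic panel for one collider summary."""
    f = mean_f(summary)
    i2 = isq_gx(summary)
    qres = exact_q(summary)
    outliers = flag_outliers(qres.per_snp, summary.k, level=level, snp_ids=summary.snp_ids)
    return DiagnosticReport(
        mean_f=f,
        i2gx=i2,
        q_exact=qres.q,
        q_df=qres.df,
        q_p=qres.p,
        per_snp_q=qres.per_snp,
        outliers=outliers,
        dilution_ivw=float(max(0.0, (f - 1.0) / f)) if f > 0 else 0.0,
        dilution_egger=i2,
        extras={"sum_f": sum_f(summary), "q_slope": qres.slope},
    )
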