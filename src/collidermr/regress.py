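"""Steps 1-2 of the Collider-Correction algorithm.

Step 1 deliberately *induces* collider bias: the outcome is regressed jointly
on the observed exposure and all SNPs (and covariates).  Conditioning on the
exposure — a collider between the genotypes and the unmeasured confounder —
contaminates the per-SNP coefficients alpha*_j and the exposure coefficient
beta*, but links them to the causal effect beta through

    alpha*_j = alpha_j + (beta - beta*) * beta_XGj.

Step 2 is the ordinary joint first-stage regression of the exposure on all
SNPs.  The two regressions share one crucial property: the estimation error
of alpha*_j is uncorrelated with the first-stage estimation error, so any
two-sample summary-data MR estimator can be applied to the pair
(beta_XGj_hat, alpha*_j_hat) to estimate the slope beta - beta*.

Everything downstream consumes the :class:`ColliderSummary` produced here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import linalg

from .datagen import IndividualData
from .errors import ConfigError, DataError, SingularDesignError

logger = logging.getLogger("collidermr")

__all__ = [
    "ColliderSummary",
    "StandardSummary",
    "TwoSampleSummary",
    "collider_summary",
    "standard_summary",
    "one_sample_standard_pair",
    "split_sample_summary",
    "write_collider_summary",
    "read_collider_summary",
]


@dataclass
class ColliderSummary:
    """Summary statistics from the collider-biased joint fits.

    Per SNP j: the first-stage association ``beta_xg[j]`` with SE
    ``se_xg[j]``, and the collider-biased direct association
    ``alpha_star[j]`` with SE ``se_alpha_star[j]``.  ``beta_star`` is the
    conditional observational exposure-outcome coefficient from the same
    joint fit.
    """

    snp_ids: list
    beta_xg: np.ndarray
    se_xg: np.ndarray
    alpha_star: np.ndarray
    se_alpha_star: np.ndarray
    beta_star: float
    se_beta_star: float
    n: int
    k: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vecs = (self.beta_xg, self.se_xg, self.alpha_star, self.se_alpha_star)
        if not all(len(v) == self.k for v in vecs) or len(self.snp_ids) != self.k:
            raise DataError("per-SNP vectors must all have length k")
        if np.any(self.se_xg <= 0) or np.any(self.se_alpha_star <= 0) or self.se_beta_star <= 0:
            raise DataError("all standard errors must be positive")
        if self.n <= self.k + 1:
            raise DataError(f"n={self.n} too small for a joint fit with k={self.k} SNPs")


@dataclass
class StandardSummary:
    """Per-SNP marginal SNP-outcome associations (regression of Y on each G_j)."""

    snp_ids: list
    beta_yg: np.ndarray
    se_yg: np.ndarray
    n: int


@dataclass
class TwoSampleSummary:
    """First-stage and SNP-outcome associations, possibly from disjoint rows.

    The unit consumed by the 'standard' IVW comparator: ``beta_xg`` from the
    exposure sample, ``beta_yg`` from the outcome sample.
    """

    snp_ids: list
    beta_xg: np.ndarray
    se_xg: np.ndarray
    beta_yg: np.ndarray
    se_yg: np.ndarray
    n_exposure: int
    n_outcome: int
    meta: dict = field(default_factory=dict)


def _check_design(data: IndividualData, covariates, allow_missing: bool):
    g = np.asarray(data.genotypes, dtype=np.float64)
    x = np.asarray(data.exposure, dtype=np.float64)
    y = np.asarray(data.outcome, dtype=np.float64)
    c = None
    if covariates is not None:
        c = np.asarray(covariates, dtype=np.float64)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != len(x):
            raise DataError("covariate row count disagrees with data")
    cols = [g, x[:, None], y[:, None]] + ([c] if c is not None else [])
    finite = np.all([np.isfinite(a).all(axis=1).all() for a in cols])
    if not finite:
        mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(g).all(axis=1)
        if c is not None:
            mask &= np.isfinite(c).all(axis=1)
        n_drop = int((~mask).sum())
        if not allow_missing:
            raise DataError(
                f"{n_drop} rows contain missing values; pass allow_missing=True "
                "for complete-case analysis"
            )
        logger.warning("complete-case analysis: dropping %d rows with missing values", n_drop)
        g, x, y = g[mask], x[mask], y[mask]
        if c is not None:
            c = c[mask]
    # Exact-duplicate SNP columns make the joint design singular; name them.
    seen: dict[bytes, int] = {}
    dup_groups: dict[int, list[int]] = {}
    for j in range(g.shape[1]):
        key = np.ascontiguousarray(g[:, j]).tobytes()
        if key in seen:
            dup_groups.setdefault(seen[key], [seen[key]]).append(j)
        else:
            seen[key] = j
    if dup_groups:
        names = ", ".join(
            "{" + ", ".join(f"g{j + 1}" for j in grp) + "}" for grp in dup_groups.values()
        )
        raise SingularDesignError(f"duplicate SNP columns: {names}")
    return g, x, y, c


def _ols(endog, exog, robust: bool) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and SEs.

    The homoskedastic path solves the normal equations by Cholesky (these
    designs are tall and well-conditioned, and this is the hot loop of every
    Monte-Carlo study); sandwich SEs go through statsmodels.  Agreement of
    the two paths is asserted in the test suite.
    """
    if robust:
        res = sm.OLS(endog, exog).fit(cov_type="HC0")
        if res.model.rank < exog.shape[1]:
            raise SingularDesignError("rank-deficient regression design")
        return res.params, res.bse
    n, p = exog.shape
    xtx = exog.T @ exog
    try:
        chol = linalg.cho_factor(xtx)
    except linalg.LinAlgError as exc:
        raise SingularDesignError(f"rank-deficient regression design: {exc}") from exc
    params = linalg.cho_solve(chol, exog.T @ endog)
    resid = endog - exog @ params
    sigma2 = float(resid @ resid) / (n - p)
    bse = np.sqrt(sigma2 * np.diag(linalg.cho_solve(chol, np.eye(p))))
    if not np.all(np.isfinite(bse)) or np.any(bse == 0):
        raise SingularDesignError("degenerate regression design (zero-variance column?)")
    return params, bse


def collider_summary(
    data: IndividualData,
    covariates=None,
    robust: bool = False,
    allow_missing: bool = False,
) -> ColliderSummary:
    """Run steps 1-2 and return the collider-biased summary statistics.

    One joint OLS of Y on (1, X, G, covariates) yields beta*_hat and the
    alpha*_j_hat; one joint OLS of X on (1, G, covariates) yields the
    beta_XGj_hat.  SEs are homoskedastic OLS SEs unless ``robust``.
    """
    g, x, y, c = _check_design(data, covariates, allow_missing)
    n, k = g.shape
    n_cov = 0 if c is None else c.shape[1]
    if n <= k + 2 + n_cov:
        raise DataError(f"n={n} too small to identify the joint fit with k={k} SNPs")

    ones = np.ones((n, 1))
    exog_y = np.hstack([ones, x[:, None], g] + ([c] if c is not None else []))
    params_y, bse_y = _ols(y, exog_y, robust)
    exog_x = np.hstack([ones, g] + ([c] if c is not None else []))
    params_x, bse_x = _ols(x, exog_x, robust)

    return ColliderSummary(
        snp_ids=[f"g{j + 1}" for j in range(k)],
        beta_xg=params_x[1 : 1 + k],
        se_xg=bse_x[1 : 1 + k],
        alpha_star=params_y[2 : 2 + k],
        se_alpha_star=bse_y[2 : 2 + k],
        beta_star=float(params_y[1]),
        se_beta_star=float(bse_y[1]),
        n=n,
        k=k,
        meta={
            "family": "gaussian",
            "robust_se": robust,
            "n_covariates": n_cov,
        },
    )


def _residualize(v: np.ndarray, c: np.ndarray | None) -> np.ndarray:
    """Residualize columns of v on an intercept plus optional covariates."""
    v = v - v.mean(axis=0)
    if c is not None:
        cc = c - c.mean(axis=0)
        coef, *_ = np.linalg.lstsq(cc, v, rcond=None)
        v = v - cc @ coef
    return v


def standard_summary(data: IndividualData, covariates=None, allow_missing: bool = False) -> StandardSummary:
    """Per-SNP marginal regressions of Y on G_j (plus covariates).

    These are the inputs of the 'standard' one-sample IVW comparator; they
    are *not* used by the Collider-Correction algorithm itself.
    """
    g, x, y, c = _check_design(data, covariates, allow_missing)
    n, k = g.shape
    n_cov = 0 if c is None else c.shape[1]
    df = n - 2 - n_cov
    if df < 1:
        raise DataError("not enough rows for per-SNP regressions")
    g_r = _residualize(g, c)
    y_r = _residualize(y[:, None], c)[:, 0]
    gss = np.sum(g_r**2, axis=0)
    if np.any(gss == 0):
        raise SingularDesignError("monomorphic SNP column in per-SNP regression")
    beta = (g_r.T @ y_r) / gss
    rss = np.sum(y_r**2) - beta**2 * gss
    se = np.sqrt(rss / df / gss)
    return StandardSummary(
        snp_ids=[f"g{j + 1}" for j in range(k)], beta_yg=beta, se_yg=se, n=n
    )


def one_sample_standard_pair(data: IndividualData, covariates=None) -> TwoSampleSummary:
    """Joint first-stage plus marginal SNP-outcome associations from the SAME rows.

    The naive one-sample input to standard IVW; its first-stage errors are
    correlated with the SNP-outcome errors, which is exactly what the
    Collider-Correction parameterization avoids.
    """
    cs = collider_summary(data, covariates=covariates)
    ss = standard_summary(data, covariates=covariates)
    return TwoSampleSummary(
        snp_ids=cs.snp_ids,
        beta_xg=cs.beta_xg,
        se_xg=cs.se_xg,
        beta_yg=ss.beta_yg,
        se_yg=ss.se_yg,
        n_exposure=cs.n,
        n_outcome=ss.n,
        meta={"overlap": "complete"},
    )


def split_sample_summary(
    data: IndividualData,
    fraction: float = 0.5,
    seed=None,
    covariates=None,
    interleave: bool = False,
) -> TwoSampleSummary:
    """Artificially split the rows in two and mimic a two-sample design.

    SNP-exposure associations come from the first split, SNP-outcome
    associations from the second, so their errors are independent by
    construction (at the cost of efficiency).  ``interleave`` uses a
    deterministic alternating split instead of a seeded random one.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigError(f"fraction must be in (0, 1), got {fraction}")
    n = data.n
    n_a = int(round(fraction * n))
    if interleave:
        mask_a = np.arange(n) % 2 == 0
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        mask_a = np.zeros(n, dtype=bool)
        mask_a[perm[:n_a]] = True
    min_rows = data.k + 3
    if mask_a.sum() < min_rows or (~mask_a).sum() < min_rows:
        raise DataError("split too small to fit the regressions")

    def _subset(mask):
        return IndividualData(
            genotypes=data.genotypes[mask],
            exposure=data.exposure[mask],
            outcome=data.outcome[mask],
            covariates=None if data.covariates is None else data.covariates[mask],
            truth=data.truth,
        )

    cov_a = covariates[mask_a] if covariates is not None else None
    cov_b = covariates[~mask_a] if covariates is not None else None
    cs = collider_summary(_subset(mask_a), covariates=cov_a)
    ss = standard_summary(_subset(~mask_a), covariates=cov_b)
    return TwoSampleSummary(
        snp_ids=cs.snp_ids,
        beta_xg=cs.beta_xg,
        se_xg=cs.se_xg,
        beta_yg=ss.beta_yg,
        se_yg=ss.se_yg,
        n_exposure=cs.n,
        n_outcome=ss.n,
        meta={"overlap": "none", "fraction": fraction},
    )


# ---------------------------------------------------------------------------
# TSV round trip: per-SNP table plus a YAML sidecar for the scalars.

def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_collider_summary(summary: ColliderSummary, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "snp_id": summary.snp_ids,
            "beta_xg": summary.beta_xg,
            "se_xg": summary.se_xg,
            "alpha_star": summary.alpha_star,
            "se_alpha_star": summary.se_alpha_star,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "beta_star": float(summary.beta_star),
        "se_beta_star": float(summary.se_beta_star),
        "n": int(summary.n),
        "k": int(summary.k),
        "meta": summary.meta,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_collider_summary(path) -> ColliderSummary:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such summary file: {path}")
    side = _sidecar(path)
    if not side.exists():
        raise DataError(f"missing sidecar {side}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = yaml.safe_load(side.read_text())
    return ColliderSummary(
        snp_ids=df["snp_id"].tolist(),
        beta_xg=df["beta_xg"].to_numpy(),
        se_xg=df["se_xg"].to_numpy(),
        alpha_star=df["alpha_star"].to_numpy(),
        se_alpha_star=df["se_alpha_star"].to_numpy(),
        beta_star=float(meta["beta_star"]),
        se_beta_star=float(meta["se_beta_star"]),
        n=int(meta["n"]),
        k=int(meta["k"]),
        meta=meta.get("meta", {}),
    )
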