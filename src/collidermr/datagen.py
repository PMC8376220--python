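"""Simulation of individual-level one-sample Mendelian randomization data.

The generating model is a linear structural equation system with a shared
unmeasured confounder U:

    X = sum_j beta_XGj G_j + e_X
    Y = beta * X + sum_j alpha_j G_j + e_Y

where G_j are independent bi-allelic dosages (Binomial(2, maf)), beta is the
causal effect of a one-unit change in the exposure X on the outcome Y, and
alpha_j are direct (horizontally pleiotropic) SNP-outcome effects.  The
confounder is folded into the residual pair (e_X, e_Y): any scalar confounder
with loadings on X and Y plus independent noise is equivalent to a bivariate
Gaussian residual with standard deviations (resid_sd_x, resid_sd_y) and
correlation resid_corr, which is the parameterization exposed here (see
:func:`residual_moments_from_confounder` for the mapping).  The reduced-form
SNP-outcome association is beta_YGj = alpha_j + beta * beta_XGj.

Pleiotropy scenarios
--------------------
``ivw``      alpha_j drawn with zero mean, independent of beta_XGj
             (InSIDE satisfied; valid for IVW-type estimators).
``egger``    alpha_j drawn with a non-zero mean, independent of beta_XGj
             (directional pleiotropy, InSIDE satisfied; MR-Egger territory).
``lad``      the first ``n_pleiotropic`` alpha_j have a non-zero mean and are
             correlated with the matching beta_XGj at ``inside_corr``; the
             remainder are exactly zero (InSIDE violated on a subset; the
             robust-regression scenario).
``fig3_toy`` alpha_j correlated with beta_XGj across *all* SNPs (InSIDE
             violated everywhere), with moderate confounding and a null
             causal effect; used to demonstrate that the first-stage
             residuals are independent of the collider-corrected residuals
             but not of the standard SNP-outcome residuals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

SCENARIOS = ("ivw", "egger", "lad", "fig3_toy")

__all__ = [
    "SCENARIOS",
    "SimulationConfig",
    "EffectVectors",
    "IndividualData",
    "Truth",
    "preset",
    "replicate_seeds",
    "residual_moments_from_confounder",
    "generate_genotypes",
    "generate_effects",
    "simulate_dataset",
    "write_individual_data",
    "read_individual_data",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the structural model.

    Parameters
    ----------
    n, k
        Number of individuals and of SNPs.
    maf
        Minor allele frequency shared by every SNP.
    beta
        True causal effect (outcome units per exposure unit).
    h2x
        Fraction of the exposure variance explained jointly by the SNPs.
    resid_sd_x, resid_sd_y, resid_corr
        Moments of the bivariate Gaussian residual pair (e_X, e_Y); the
        correlation encodes the strength of confounding.
    scenario
        Pleiotropy regime, one of :data:`SCENARIOS`.
    beta_xg_mean, beta_xg_sd
        Moments of the raw SNP-exposure effect distribution (rescaled per
        draw so the genetic variance of X matches ``h2x`` exactly).
    pleiotropy_mean, pleiotropy_sd
        Moments of the direct effects alpha_j (mean ignored in ``ivw``).
    inside_corr
        Target correlation between alpha_j and beta_XGj on the
        InSIDE-violating subset (scenarios ``lad`` and ``fig3_toy``).
    n_pleiotropic
        Number of SNPs with non-zero alpha_j in scenario ``lad``.
    seed
        Default RNG seed used when :func:`simulate_dataset` is not given one.
    """

    n: int
    k: int = 50
    maf: float = 0.3
    beta: float = 0.5
    h2x: float = 0.015
    resid_sd_x: float = 1.0
    resid_sd_y: float = 0.69
    resid_corr: float = 0.9
    scenario: str = "ivw"
    beta_xg_mean: float = 0.026
    beta_xg_sd: float = 0.007
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.004
    inside_corr: float = 0.5
    n_pleiotropic: int = 15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")
        if not 0.0 <= self.maf < 0.5:
            raise ConfigError(f"maf must be in [0, 0.5), got {self.maf}")
        if not 0.0 <= self.h2x < 1.0:
            raise ConfigError(f"h2x must be in [0, 1), got {self.h2x}")
        if not -1.0 < self.resid_corr < 1.0:
            raise ConfigError(f"resid_corr must be in (-1, 1), got {self.resid_corr}")
        if self.resid_sd_x <= 0 or self.resid_sd_y <= 0:
            raise ConfigError("residual standard deviations must be positive")
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.n_pleiotropic < 0 or (
            self.scenario == "lad" and self.n_pleiotropic > self.k
        ):
            raise ConfigError(
                f"n_pleiotropic must be in [0, k], got {self.n_pleiotropic} with k={self.k}"
            )
        if not -1.0 < self.inside_corr < 1.0:
            raise ConfigError(f"inside_corr must be in (-1, 1), got {self.inside_corr}")
        if self.pleiotropy_sd < 0 or self.beta_xg_sd < 0:
            raise ConfigError("effect standard deviations must be non-negative")

    @property
    def genetic_variance(self) -> float:
        """Variance of X attributable to the SNPs, h2x/(1-h2x) * sd_x^2."""
        return self.h2x / (1.0 - self.h2x) * self.resid_sd_x**2


@dataclass(frozen=True)
class EffectVectors:
    """True per-SNP effects: beta_xg on the exposure, alpha on the outcome."""

    beta_xg: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        if self.beta_xg.shape != self.alpha.shape or self.beta_xg.ndim != 1:
            raise ConfigError("beta_xg and alpha must be 1-D vectors of equal length")


@dataclass(frozen=True)
class Truth:
    """Generating parameters attached to a simulated dataset for oracle checks."""

    config: SimulationConfig
    effects: EffectVectors
    beta_yg: np.ndarray  # reduced-form alpha + beta * beta_xg


@dataclass(frozen=True)
class IndividualData:
    """An individual-level dataset: dosages, exposure, outcome, covariates."""

    genotypes: np.ndarray
    exposure: np.ndarray
    outcome: np.ndarray
    covariates: np.ndarray | None = None
    truth: Truth | None = None

    def __post_init__(self) -> None:
        g, x, y = self.genotypes, self.exposure, self.outcome
        if g.ndim != 2 or x.ndim != 1 or y.ndim != 1:
            raise DataError("genotypes must be 2-D; exposure and outcome 1-D")
        if not (g.shape[0] == x.shape[0] == y.shape[0]):
            raise DataError("row counts of genotypes, exposure and outcome disagree")
        if self.covariates is not None and self.covariates.shape[0] != x.shape[0]:
            raise DataError("covariate row count disagrees with exposure")
        if not np.isin(g, (0, 1, 2)).all():
            raise DataError("genotype dosages must be 0, 1 or 2")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise DataError("exposure/outcome contain non-finite values")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def k(self) -> int:
        return self.genotypes.shape[1]


# Named study conditions.  "ivw" with the class defaults *is* the main
# simulation setting (beta = 0.5, strong confounding rho = 0.9 calibrated so
# the conditional observational coefficient is ~1.12 and the collider-
# correction slope ~-0.62).  "fig3_toy" is the residual-independence
# demonstration: moderate confounding (rho = 0.5), InSIDE violated across all
# SNPs at correlation ~0.45, and a null causal effect so that the standard
# SNP-outcome residual correlation equals the residual correlation.
_PRESETS: dict[str, dict] = {
    "ivw": dict(scenario="ivw", pleiotropy_mean=0.0),
    "egger": dict(scenario="egger", pleiotropy_mean=0.01),
    "lad": dict(scenario="lad", pleiotropy_mean=0.01, inside_corr=0.5, n_pleiotropic=15),
    "fig3_toy": dict(
        scenario="fig3_toy",
        beta=0.0,
        resid_corr=0.5,
        resid_sd_y=1.0,
        pleiotropy_mean=0.0,
        inside_corr=0.45,
    ),
}


def preset(name: str, n: int, seed: int | None = None, **overrides) -> SimulationConfig:
    """Return the :class:`SimulationConfig` for a named study condition."""
    if name not in _PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(n=n, seed=seed, **kwargs)


def replicate_seeds(root_seed: int, n_replicates: int) -> list[np.random.SeedSequence]:
    """Deterministic child seed sequences for independent replicates.

    Replicate ``i`` is reproducible in isolation as
    ``np.random.SeedSequence(root_seed).spawn(i + 1)[i]``.
    """
    return np.random.SeedSequence(root_seed).spawn(n_replicates)


def residual_moments_from_confounder(
    beta_ux: float, beta_uy: float, noise_sd_x: float, noise_sd_y: float
) -> tuple[float, float, float]:
    """Map a scalar-confounder parameterization to bivariate residual moments.

    For e_X = beta_ux * U + eps_X and e_Y = beta_uy * U + eps_Y with U a
    standard normal and independent noises, returns
    ``(resid_sd_x, resid_sd_y, resid_corr)``.
    """
    var_x = beta_ux**2 + noise_sd_x**2
    var_y = beta_uy**2 + noise_sd_y**2
    if var_x <= 0 or var_y <= 0:
        raise ConfigError("degenerate residual variance")
    rho = beta_ux * beta_uy / np.sqrt(var_x * var_y)
    return float(np.sqrt(var_x)), float(np.sqrt(var_y)), float(rho)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_genotypes(n: int, k: int, maf: float, seed=None) -> np.ndarray:
    """Draw an n x k dosage matrix, each entry Binomial(2, maf), columns iid."""
    if n < 1 or k < 1:
        raise ConfigError("n and k must be positive")
    if not 0.0 <= maf < 0.5:
        raise ConfigError(f"maf must be in [0, 0.5), got {maf}")
    rng = _as_rng(seed)
    return rng.binomial(2, maf, size=(n, k)).astype(np.float64)


def generate_effects(config: SimulationConfig, seed=None) -> EffectVectors:
    """Draw true SNP effects for one replicate under ``config.scenario``.

    SNP-exposure effects are drawn N(beta_xg_mean, beta_xg_sd^2) and rescaled
    so the genetic variance sum(beta_xg^2) * 2*maf*(1-maf) equals
    ``config.genetic_variance`` exactly, pinning the variance explained at
    h2x.  Direct effects alpha are drawn per the scenario (module docstring).
    """
    rng = _as_rng(seed if seed is not None else config.seed)
    k = config.k
    var_per_allele = 2.0 * config.maf * (1.0 - config.maf)
    if var_per_allele <= 0 and config.h2x > 0:
        raise ConfigError("h2x > 0 requires maf > 0")

    raw = rng.normal(config.beta_xg_mean, config.beta_xg_sd, size=k)
    if config.h2x > 0:
        scale = np.sqrt(config.genetic_variance / (np.sum(raw**2) * var_per_allele))
        beta_xg = raw * scale
    else:
        beta_xg = np.zeros(k)

    sd = config.pleiotropy_sd
    if config.scenario == "ivw":
        alpha = rng.normal(0.0, sd, size=k) if sd > 0 else np.zeros(k)
    elif config.scenario == "egger":
        alpha = config.pleiotropy_mean + (rng.normal(0.0, sd, size=k) if sd > 0 else 0.0)
        alpha = np.broadcast_to(alpha, (k,)).astype(float).copy()
    else:  # lad / fig3_toy: alpha correlated with beta_xg on a subset
        m = k if config.scenario == "fig3_toy" else config.n_pleiotropic
        r = config.inside_corr
        if m < 2:
            raise ConfigError("correlated pleiotropy needs at least 2 SNPs in the subset")
        if sd == 0 and r != 0:
            raise ConfigError("inside_corr != 0 is infeasible with pleiotropy_sd = 0")
        alpha = np.zeros(k)
        if sd > 0:
            sub = beta_xg[:m]
            z = (sub - sub.mean()) / sub.std(ddof=1)
            w = rng.standard_normal(m)
            alpha[:m] = config.pleiotropy_mean + sd * (r * z + np.sqrt(1.0 - r**2) * w)
    return EffectVectors(beta_xg=beta_xg, alpha=alpha)


def simulate_dataset(config: SimulationConfig, seed=None) -> IndividualData:
    """Simulate one individual-level dataset; the truth slot is populated.

    The residual pair is realized through a shared standard-normal confounder
    U with loadings chosen to reproduce (resid_sd_x, resid_sd_y, resid_corr)
    exactly.
    """
    rng = _as_rng(seed if seed is not None else config.seed)
    effects = generate_effects(config, rng)
    g = generate_genotypes(config.n, config.k, config.maf, rng)

    rho = config.resid_corr
    sx, sy = config.resid_sd_x, config.resid_sd_y
    a = np.sqrt(abs(rho))
    u = rng.standard_normal(config.n)
    e_x = sx * (a * u + np.sqrt(1.0 - abs(rho)) * rng.standard_normal(config.n))
    e_y = sy * (np.sign(rho) * a * u + np.sqrt(1.0 - abs(rho)) * rng.standard_normal(config.n))

    x = g @ effects.beta_xg + e_x
    y = config.beta * x + g @ effects.alpha + e_y
    beta_yg = effects.alpha + config.beta * effects.beta_xg
    return IndividualData(
        genotypes=g,
        exposure=x,
        outcome=y,
        truth=Truth(config=config, effects=effects, beta_yg=beta_yg),
    )


# ---------------------------------------------------------------------------
# Delimited-text round trip: TSV with columns iid, x, y, g1..gk (plus any
# covariates), truth in a JSON sidecar `<path>.truth.json`.

def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".truth.json")


def write_individual_data(data: IndividualData, path) -> Path:
    path = Path(path)
    cols = {"iid": np.arange(data.n), "x": data.exposure, "y": data.outcome}
    for j in range(data.k):
        cols[f"g{j + 1}"] = data.genotypes[:, j].astype(np.int64)
    if data.covariates is not None:
        for c in range(data.covariates.shape[1]):
            cols[f"c{c + 1}"] = data.covariates[:, c]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")
    if data.truth is not None:
        payload = {
            "config": dataclasses.asdict(data.truth.config),
            "beta_xg": data.truth.effects.beta_xg.tolist(),
            "alpha": data.truth.effects.alpha.tolist(),
            "beta_yg": data.truth.beta_yg.tolist(),
        }
        _sidecar(path).write_text(json.dumps(payload, indent=1))
    return path


def read_individual_data(path) -> IndividualData:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such data file: {path}")
    df = pd.read_csv(path, sep="\t")
    g_cols = [c for c in df.columns if c.startswith("g") and c[1:].isdigit()]
    c_cols = [c for c in df.columns if c.startswith("c") and c[1:].isdigit()]
    if not g_cols or "x" not in df.columns or "y" not in df.columns:
        raise DataError(f"{path} lacks the expected iid/x/y/g1..gk columns")
    g_cols = sorted(g_cols, key=lambda c: int(c[1:]))
    truth = None
    side = _sidecar(path)
    if side.exists():
        payload = json.loads(side.read_text())
        cfg = SimulationConfig(**payload["config"])
        eff = EffectVectors(
            beta_xg=np.asarray(payload["beta_xg"]), alpha=np.asarray(payload["alpha"])
        )
        truth = Truth(config=cfg, effects=eff, beta_yg=np.asarray(payload["beta_yg"]))
    return IndividualData(
        genotypes=df[g_cols].to_numpy(dtype=np.float64),
        exposure=df["x"].to_numpy(dtype=np.float64),
        outcome=df["y"].to_numpy(dtype=np.float64),
        covariates=df[sorted(c_cols, key=lambda c: int(c[1:]))].to_numpy(dtype=np.float64)
        if c_cols
        else None,
        truth=truth,
    )
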