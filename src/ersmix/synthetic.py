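"""Synthetic multipollutant cohorts.

Generates seeded cohorts with the statistical structure the ERS engines
assume: block-correlated log-normal exposure biomarkers, a right-skewed
continuous outcome that is linear in the log10 exposures with sparse main
and pairwise-interaction effects, demographic covariates including a
urine-dilution analogue, limit-of-detection censoring, and binary plus
survival endpoints driven by the same latent exposure score.

Default parameter values emulate the published application that motivated
the package: 20 urinary/blood metal biomarkers with their observed
geometric means and geometric SDs, correlation blocks matching the
empirical Spearman structure (an arsenic-species cluster, a broad urinary
metal cluster, a blood lead-cadmium pair), and a continuous oxidative
stress marker (GGT-like) with SD(log10 Y) near 0.21.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "MixtureCohort",
    "simulate_cohort",
    "apply_lod",
    "dichotomize_outcome",
    "DEFAULT_EXPOSURES",
]

# (name, geometric mean, geometric SD) for the default 20-biomarker panel,
# raw concentration scale.  Ordered so that correlation blocks are
# contiguous: 4 arsenic species, 11 urinary metals, blood Pb/Cd pair,
# 3 independent markers.
DEFAULT_EXPOSURES: list[tuple[str, float, float]] = [
    # arsenic-species block (high mutual rank correlation)
    ("arsenous_acid", 0.65, 1.91),
    ("arsenic_acid", 0.68, 1.21),
    ("arsenocholine", 0.30, 1.91),
    ("mma", 0.73, 1.85),
    # urinary-metal block (moderate mutual correlation)
    ("total_arsenic", 8.88, 3.17),
    ("dma", 3.85, 2.27),
    ("cadmium_u", 0.24, 2.77),
    ("lead_u", 0.51, 2.47),
    ("cobalt", 0.34, 2.26),
    ("thallium", 0.14, 2.09),
    ("cesium", 4.22, 2.00),
    ("barium", 1.20, 2.72),
    ("uranium", 0.01, 2.65),
    ("tungsten", 0.07, 2.77),
    ("molybdenum", 38.64, 2.42),
    # blood pair
    ("lead_b", 1.32, 2.00),
    ("cadmium_b", 0.37, 2.22),
    # weakly correlated singletons
    ("mercury_b", 0.93, 2.68),
    ("antimony", 0.06, 2.21),
    ("arsenobetaine", 1.99, 5.19),
]

_DEFAULT_BLOCKS = [(4, 0.65), (11, 0.45), (2, 0.35), (3, 0.0)]

# Sparse truth: the panel's historically important metals, effect sizes on
# the per-SD log10 scale, signs as reported for the oxidative-stress marker.
_DEFAULT_BETA_MAIN = {
    "lead_b": 0.31,
    "cadmium_u": 0.22,
    "dma": 0.28,
    "cobalt": -0.14,
    "mma": -0.10,
    "barium": 0.05,
}
_DEFAULT_BETA_INTER = {
    ("cesium", "lead_b"): -0.15,
    ("mercury_b", "arsenic_acid"): -0.15,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for :func:`simulate_cohort`.

    Effect sizes in ``beta_main``/``beta_inter`` act on the centered log10
    concentration scale (one unit = a ten-fold increase in the raw
    concentration), matching how penalized-regression coefficients for
    log10-transformed biomarkers are conventionally reported.
    """

    n: int = 9664
    p: int = 20
    block_spec: list[tuple[int, float]] = field(
        default_factory=lambda: list(_DEFAULT_BLOCKS)
    )
    gm: tuple[float, ...] | None = None
    gsd: tuple[float, ...] | None = None
    exposure_names: tuple[str, ...] | None = None
    lod_quantile: float = 0.05
    beta_main: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BETA_MAIN)
    )
    beta_inter: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_BETA_INTER)
    )
    gamma_z: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.03,
            "sex": -0.08,
            "bmi": 0.04,
            "creatinine": 0.05,
            "smoking_current": 0.03,
            "education_lt_hs": 0.01,
        }
    )
    intercept: float = 1.30  # log10 scale; 10**1.30 ~ 20 U/L baseline
    noise_sd: float = 0.19
    binary_quantile: float = 0.9
    surv_spec: dict[str, float] = field(
        default_factory=lambda: {
            "baseline_rate": 0.012,  # events / person-year
            "log_hr_per_sd": 0.10,
            "followup_min": 2.0,
            "followup_max": 7.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        sizes = sum(b for b, _ in self.block_spec)
        if sizes != self.p:
            raise ValueError(
                f"block sizes sum to {sizes}, expected p={self.p}"
            )
        for i, (size, rho) in enumerate(self.block_spec):
            if not (-1.0 < rho < 1.0):
                raise ValueError(f"block {i}: correlation {rho} not in (-1, 1)")
            if size < 1:
                raise ValueError(f"block {i}: size must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 < self.binary_quantile < 1.0):
            raise ValueError("binary_quantile must be in (0, 1)")
        if not (0.0 <= self.lod_quantile < 1.0):
            raise ValueError("lod_quantile must be in [0, 1)")


@dataclass
class MixtureCohort:
    """Subjects x (exposures, covariates, outcomes) with LOD metadata.

    ``truth`` retains the generating effect sizes and per-subject latent
    exposure score; it exists for testing and is never consumed by the
    estimation engines.
    """

    exposures: pd.DataFrame
    covariates: pd.DataFrame
    outcome: pd.Series
    binary: pd.Series | None = None
    survival: pd.DataFrame | None = None  # columns: entry_age, exit_age, event
    lod: pd.Series | None = None
    truth: dict | None = None
    log_scale: bool = False

    @property
    def n(self) -> int:
        return len(self.exposures)

    @property
    def exposure_names(self) -> list[str]:
        return list(self.exposures.columns)

    def subset(self, idx: np.ndarray) -> "MixtureCohort":
        """Row subset (positional), preserving metadata."""
        return MixtureCohort(
            exposures=self.exposures.iloc[idx].reset_index(drop=True),
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            outcome=self.outcome.iloc[idx].reset_index(drop=True),
            binary=None if self.binary is None else self.binary.iloc[idx].reset_index(drop=True),
            survival=None if self.survival is None else self.survival.iloc[idx].reset_index(drop=True),
            lod=self.lod,
            truth=self.truth,
            log_scale=self.log_scale,
        )

    def validate(self) -> None:
        if self.exposures.isna().any().any() or self.outcome.isna().any():
            raise ValueError("cohort contains missing values")
        if not self.log_scale and (self.outcome <= 0).any():
            raise ValueError("outcome must be positive on the raw scale")
        if self.survival is not None:
            bad = self.survival["entry_age"] >= self.survival["exit_age"]
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} survival rows with entry_age >= exit_age"
                )


def apply_lod(values: np.ndarray, lod: float) -> np.ndarray:
    """Substitute values below the limit of detection by LOD/sqrt(2).

    This is the conventional single-imputation rule used in national
    biomonitoring data; entries at or above the LOD pass through unchanged.
    """
    if lod <= 0:
        raise ValueError("lod must be > 0")
    values = np.asarray(values, dtype=float)
    return np.where(values < lod, lod / np.sqrt(2.0), values)


def dichotomize_outcome(y: np.ndarray, level: float) -> tuple[np.ndarray, float]:
    """Indicator of y >= empirical quantile(level).

    The quantile uses the linear-interpolation convention
    (``numpy.quantile`` default); the threshold actually used is returned
    alongside the indicator so downstream reports can state it.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if np.ptp(y) == 0.0:
        raise ValueError("degenerate outcome: all values equal, cannot dichotomize")
    threshold = float(np.quantile(y, level))
    return (y >= threshold).astype(int), threshold


def _block_correlation_matrix(block_spec: list[tuple[int, float]]) -> np.ndarray:
    blocks = []
    for i, (size, rho) in enumerate(block_spec):
        block = np.full((size, size), rho)
        np.fill_diagonal(block, 1.0)
        # equicorrelation is PD iff rho > -1/(size-1)
        if size > 1 and rho <= -1.0 / (size - 1):
            raise ValueError(
                f"block {i} (size {size}, rho {rho}) implies a "
                "non-positive-definite correlation matrix"
            )
        blocks.append(block)
    p = sum(b.shape[0] for b in blocks)
    corr = np.zeros((p, p))
    at = 0
    for b in blocks:
        k = b.shape[0]
        corr[at : at + k, at : at + k] = b
        at += k
    return corr


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics modeled on a US adult survey population."""
    age = np.clip(rng.normal(49.2, 17.2, n), 20.0, 85.0)
    sex = rng.binomial(1, 0.508, n)  # 1 = female
    race = rng.choice(
        ["mexican_american", "other_hispanic", "nh_white", "nh_black", "other"],
        size=n,
        p=[0.167, 0.081, 0.466, 0.204, 0.082],
    )
    education = rng.choice(
        ["lt_hs", "hs", "gt_hs"], size=n, p=[0.269, 0.519, 0.212]
    )
    smoking = rng.choice(
        ["never", "former", "current"], size=n, p=[0.542, 0.207, 0.251]
    )
    bmi = np.clip(rng.normal(28.8, 6.7, n), 15.0, 70.0)
    # dilution covariate (urinary creatinine analogue), log-normal
    creatinine = np.exp(rng.normal(np.log(110.0), 0.6, n))
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "race": pd.Categorical(race),
            "education": pd.Categorical(education),
            "smoking": pd.Categorical(smoking),
            "bmi": bmi,
            "creatinine": creatinine,
        }
    )


def _covariate_linear_term(Z: pd.DataFrame, gamma_z: dict[str, float]) -> np.ndarray:
    """Linear predictor of the covariates, standardized continuous terms."""
    out = np.zeros(len(Z))
    for key, g in gamma_z.items():
        if key in ("age", "bmi", "creatinine"):
            col = Z[key].to_numpy(dtype=float)
            out += g * (col - col.mean()) / col.std()
        elif key == "sex":
            out += g * Z["sex"].to_numpy(dtype=float)
        elif key.startswith("smoking_"):
            out += g * (Z["smoking"] == key.split("_", 1)[1]).to_numpy(dtype=float)
        elif key.startswith("education_"):
            out += g * (Z["education"] == key.split("_", 1)[1]).to_numpy(dtype=float)
        elif key.startswith("race_"):
            out += g * (Z["race"] == key.split("_", 1)[1]).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate effect key: {key!r}")
    return out


def simulate_cohort(config: SimulationConfig) -> MixtureCohort:
    """Draw one cohort from the configured generative model.

    The exposure matrix is ``10**(log10(gm) + log10(gsd) * G)`` where ``G``
    is block-correlated standard Gaussian; the continuous outcome is
    log10-linear in ``G`` (sparse mains + pairwise interactions) and the
    covariates, with Gaussian noise.  LOD censoring replaces the lowest
    ``lod_quantile`` fraction of each biomarker by LOD/sqrt(2).  Identical
    (config, seed) yields a bitwise-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p

    if config.exposure_names is not None:
        names = list(config.exposure_names)
        if len(names) != p:
            raise ValueError("exposure_names length must equal p")
    elif p == len(DEFAULT_EXPOSURES):
        names = [e[0] for e in DEFAULT_EXPOSURES]
    else:
        names = [f"metal_{j + 1:02d}" for j in range(p)]
    if len(set(names)) != p:
        raise ValueError("duplicate exposure names")

    if config.gm is not None:
        gm = np.asarray(config.gm, dtype=float)
        gsd = np.asarray(config.gsd, dtype=float)
    elif p == len(DEFAULT_EXPOSURES) and config.exposure_names is None:
        gm = np.array([e[1] for e in DEFAULT_EXPOSURES])
        gsd = np.array([e[2] for e in DEFAULT_EXPOSURES])
    else:
        gm = np.ones(p)
        gsd = np.full(p, 2.0)
    if gm.shape != (p,) or gsd.shape != (p,):
        raise ValueError("gm and gsd must have length p")
    if (gm <= 0).any() or (gsd <= 1).any():
        raise ValueError("gm must be > 0 and gsd > 1")

    corr = _block_correlation_matrix(config.block_spec)
    chol = np.linalg.cholesky(corr)
    G = rng.standard_normal((n, p)) @ chol.T

    log10_E = np.log10(gm)[None, :] + np.log10(gsd)[None, :] * G
    E = 10.0 ** log10_E

    # LOD = the configured lower quantile of the marginal log-normal
    name_to_idx = {nm: j for j, nm in enumerate(names)}
    if config.lod_quantile > 0.0:
        from scipy.stats import norm

        z_lod = norm.ppf(config.lod_quantile)
        lod_vals = 10.0 ** (np.log10(gm) + np.log10(gsd) * z_lod)
        for j in range(p):
            E[:, j] = apply_lod(E[:, j], lod_vals[j])
        lod = pd.Series(lod_vals, index=names)
    else:
        lod = pd.Series(np.zeros(p), index=names)

    Z = _draw_covariates(n, rng)

    unknown = [nm for nm in config.beta_main if nm not in name_to_idx]
    unknown += [nm for pair in config.beta_inter for nm in pair if nm not in name_to_idx]
    if unknown:
        raise ValueError(
            f"effect sizes reference unknown exposures {sorted(set(unknown))}; "
            f"available: {names}"
        )

    # centered log10 concentrations (pre-censoring latent), the scale on
    # which log-linear mixture coefficients are conventionally reported
    L = np.log10(gsd)[None, :] * G
    score = np.zeros(n)
    for nm, b in config.beta_main.items():
        score += b * L[:, name_to_idx[nm]]
    for (a, bnm), b in config.beta_inter.items():
        score += b * L[:, name_to_idx[a]] * L[:, name_to_idx[bnm]]

    log10_Y = (
        config.intercept
        + score
        + _covariate_linear_term(Z, config.gamma_z)
        + rng.normal(0.0, config.noise_sd, n)
    )
    Y = pd.Series(10.0 ** log10_Y, name="outcome")

    # binary endpoint: noisy liability sharing the latent exposure score
    liability = score + rng.logistic(0.0, 1.0, n)
    binary, _thr = dichotomize_outcome(liability, config.binary_quantile)

    # survival with age time-scale: delayed entry at the subject's age,
    # exponential hazard scaled by the standardized latent score
    ss = config.surv_spec
    score_sd = score.std() if score.std() > 0 else 1.0
    rate = ss["baseline_rate"] * np.exp(
        ss["log_hr_per_sd"] * (score - score.mean()) / score_sd
    )
    entry = Z["age"].to_numpy(dtype=float)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(ss["followup_min"], ss["followup_max"], n)
    event = (t_event <= t_cens).astype(int)
    exit_age = entry + np.minimum(t_event, t_cens)
    survival = pd.DataFrame(
        {"entry_age": entry, "exit_age": exit_age, "event": event}
    )

    cohort = MixtureCohort(
        exposures=pd.DataFrame(E, columns=names),
        covariates=Z,
        outcome=Y,
        binary=pd.Series(binary, name="binary"),
        survival=survival,
        lod=lod,
        truth={
            "beta_main": dict(config.beta_main),
            "beta_inter": {f"{a}x{b}": v for (a, b), v in config.beta_inter.items()},
            "score": score,
            "noise_sd": config.noise_sd,
            "config": _config_to_jsonable(config),
        },
        log_scale=False,
    )
    cohort.validate()
    return cohort


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["beta_inter"] = {f"{a}x{b}": v for (a, b), v in config.beta_inter.items()}
    return d


def write_cohort(cohort: MixtureCohort, path: str | Path, header_comment: str | None = None) -> None:
    """Write the cohort as one CSV row per subject plus a JSON truth sidecar."""
    path = Path(path)
    table = pd.concat(
        [cohort.exposures, cohort.covariates, cohort.outcome.rename("outcome")],
        axis=1,
    )
    if cohort.binary is not None:
        table["binary"] = cohort.binary
    if cohort.survival is not None:
        table = pd.concat([table, cohort.survival], axis=1)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, index=False)
    if cohort.truth is not None:
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in cohort.truth.items()
        }
        Path(str(path) + ".truth.json").write_text(json.dumps(truth, indent=1))
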