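"""Synthetic oncology cohorts with known ground truth.

A single latent severity factor drives all labs (so the biomarker panel
shows realistic collinearity, which is what makes the Pearson/LASSO
screening stage meaningful), and the hazard is a step function of the
number of adverse score components — so the true prognostic structure is
exactly the structure the INS assumes, with known thresholds and log
hazard ratios for recovery tests.

Defaults mirror the scale of a large multicenter cancer cohort: 5,221
patients, TNM stages I-IV, right-censored overall survival in months with
stratum-wise death proportions rising from roughly one quarter to roughly
two thirds across INS 1-5 and ~45% overall mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .biomarkers import compute_panel
from .data_model import Cohort
from .scoring import INSConfig, INS_2022, dichotomize

__all__ = ["SimConfig", "simulate_cohort", "make_changepoint_series"]

TUMOR_TYPES = ("gastric", "colorectal", "lung", "esophageal", "breast", "other")
TUMOR_PROBS = (0.20, 0.22, 0.20, 0.10, 0.10, 0.18)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the bundled study conditions."""

    n: int = 5221
    seed: int = 0
    severity: Literal["beta", "uniform"] = "beta"
    severity_beta: tuple[float, float] = (2.0, 2.0)
    #: per-component true thresholds and adverse directions
    score_config: INSConfig = INS_2022
    #: log hazard ratio per adverse component (e^{4x} ~ 4.2 across strata)
    log_hr_per_point: float = 0.36
    #: baseline Weibull (shape, scale in months) for a zero-score patient
    weibull_shape: float = 1.2
    weibull_scale: float = 260.0
    #: confounder log-hazard effects (Model-b adjustment targets)
    beta_age_per_decade: float = 0.10
    beta_stage_per_level: float = 0.15
    beta_male: float = 0.05
    #: accrual window: administrative censoring uniform on this interval
    admin_censor_range: tuple[float, float] = (36.0, 126.0)
    #: independent exponential dropout rate (per month)
    dropout_rate: float = 1.0 / 400.0
    #: lab noise multiplier (0 gives noise-free labs)
    noise_scale: float = 1.0
    missing_optional_frac: float = 0.05

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")


def _severity(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.severity == "uniform":
        return rng.uniform(0, 1, cfg.n)
    a, b = cfg.severity_beta
    return rng.beta(a, b, cfg.n)


def _labs(cfg: SimConfig, u: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n, s = cfg.n, cfg.noise_scale

    def N(sd):
        return rng.normal(0.0, sd * s, n)

    sex = np.where(rng.random(n) < 0.586, "male", "female")
    height = np.where(sex == "male", rng.normal(170, 6, n), rng.normal(158, 5.5, n))
    bmi = np.clip(23.5 - 3.5 * u + N(2.5), 14, 38)
    weight = bmi * (height / 100.0) ** 2

    lymph = np.clip(np.exp(np.log(1.8) - 0.55 * u + N(0.28)), 0.2, 5.0)
    crp = np.clip(np.exp(0.0 + 3.8 * u + N(0.9)), 0.1, 300.0)
    albumin = np.clip(45.0 - 12.0 * u + N(2.5), 20, 55)
    neut = np.clip(np.exp(np.log(3.2) + 0.55 * u + N(0.25)), 0.8, 20.0)
    plt = np.clip(np.exp(np.log(220) + 0.25 * u + N(0.20)), 50, 800)
    wbc = np.clip(neut + lymph + 0.6 + N(0.4), 1.5, 30.0)
    rbc = np.clip(4.7 - 0.8 * u + N(0.35), 2.0, 7.0)
    hgb = np.clip(142.0 - 25.0 * u + N(10.0), 60, 190)
    glucose = np.clip(5.2 + 1.0 * u + N(0.8), 2.5, 20.0)
    tprot = np.clip(albumin + rng.normal(28, 3, n), 40, 95)
    chol = np.clip(4.8 - 0.8 * u + N(0.8), 1.5, 10.0)

    df = pd.DataFrame({
        "sex": sex, "height": height, "weight": weight,
        "wbc": wbc, "neutrophils": neut, "lymphocytes": lymph,
        "platelets": plt, "rbc": rbc, "hemoglobin": hgb,
        "albumin": albumin, "crp": crp, "glucose": glucose,
        "total_protein": tprot, "cholesterol": chol,
    })
    if cfg.missing_optional_frac > 0:
        for c in ("total_protein", "cholesterol"):
            m = rng.random(n) < cfg.missing_optional_frac
            df.loc[m, c] = np.nan
    return df


def _covariates(cfg: SimConfig, u: np.ndarray, rng: np.random.Generator
                ) -> pd.DataFrame:
    n = cfg.n
    age = np.clip(rng.normal(59.4, 10.5, n) + 6.0 * (u - 0.5), 18, 95)
    stage_latent = u + rng.normal(0, 0.25, n)
    qs = np.quantile(stage_latent, [0.25, 0.50, 0.75])
    stage_idx = np.digitize(stage_latent, qs)  # 0..3
    stage = np.array(["I", "II", "III", "IV"])[stage_idx]
    df = pd.DataFrame({
        "age": age,
        "tnm_stage": stage,
        "tumor_type": rng.choice(TUMOR_TYPES, n, p=TUMOR_PROBS),
        "surgery": rng.random(n) < 0.60,
        "radiotherapy": rng.random(n) < 0.25,
        "chemotherapy": rng.random(n) < 0.50,
        "hypertension": rng.random(n) < 0.22,
        "diabetes": rng.random(n) < 0.12,
        "smoking": rng.random(n) < 0.32,
        "drinking": rng.random(n) < 0.25,
        "family_history": rng.random(n) < 0.15,
    })
    df["_stage_idx"] = stage_idx
    return df


def simulate_cohort(config: SimConfig = SimConfig(),
                    seed: int | None = None) -> tuple[Cohort, dict]:
    """Generate a cohort plus its ground-truth record.

    Ground truth holds the per-patient adverse bits and true stratum
    (computed from the generated labs at the configured true thresholds),
    the true per-point log hazard ratio, and the thresholds themselves.
    Deterministic given the seed.
    """
    cfg = config if seed is None else replace(config, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    u = _severity(cfg, rng)
    labs = _labs(cfg, u, rng)
    cov = _covariates(cfg, u, rng)
    df = pd.concat([labs, cov.drop(columns="_stage_idx")], axis=1)
    df.insert(0, "patient_id", [f"P{i:05d}" for i in range(cfg.n)])
    df["bmi"] = df["weight"] / (df["height"] / 100.0) ** 2

    # true adverse bits from the realized labs at the true thresholds
    panel = compute_panel(df)
    bits = np.column_stack([
        dichotomize(panel[c.index_name].to_numpy(float), c.threshold, c.direction)
        for c in cfg.score_config.components
    ])
    score = bits.sum(axis=1)

    lp = (cfg.log_hr_per_point * score
          + cfg.beta_age_per_decade * (cov["age"].to_numpy() - 59.4) / 10.0
          + cfg.beta_stage_per_level * cov["_stage_idx"].to_numpy()
          + cfg.beta_male * (df["sex"] == "male").to_numpy(float))
    uni = rng.uniform(size=cfg.n)
    t_event = cfg.weibull_scale * (-np.log(uni) / np.exp(lp)) ** (1.0 / cfg.weibull_shape)
    c_admin = rng.uniform(*cfg.admin_censor_range, cfg.n)
    if cfg.dropout_rate > 0:
        c_drop = rng.exponential(1.0 / cfg.dropout_rate, cfg.n)
    else:
        c_drop = np.full(cfg.n, np.inf)
    c_all = np.minimum(c_admin, c_drop)
    event = (t_event <= c_all).astype(int)
    os_time = np.minimum(t_event, c_all)
    df["os_time"] = np.round(os_time, 3)
    df["event"] = event

    cohort = Cohort(df, provenance=f"simulated seed={cfg.seed}")
    truth = {
        "seed": cfg.seed,
        "log_hr_per_point": cfg.log_hr_per_point,
        "thresholds": {c.index_name: c.threshold
                       for c in cfg.score_config.components},
        "directions": {c.index_name: c.direction
                       for c in cfg.score_config.components},
        "bits": bits.astype(int),
        "raw_score": score.astype(int),
        "stratum": (score + 1).astype(int),
        "severity": u,
    }
    return cohort, truth


def make_changepoint_series(n: int, threshold: float = 50.0, hr: float = 2.5,
                            seed: int | None = None,
                            value_range: tuple[float, float] = (0.0, 100.0),
                            weibull_shape: float = 1.2,
                            weibull_scale: float = 80.0,
                            censor_range: tuple[float, float] = (24.0, 96.0),
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One biomarker with a step hazard below the threshold.

    Values are uniform on ``value_range``; subjects with value < threshold
    carry hazard ratio ``hr``. Used for cutpoint-recovery experiments.
    """
    if n < 100:
        raise ValueError("need n >= 100")
    rng = np.random.default_rng(seed)
    values = rng.uniform(*value_range, n)
    lp = np.log(hr) * (values < threshold)
    t_event = weibull_scale * (-np.log(rng.uniform(size=n))
                               / np.exp(lp)) ** (1.0 / weibull_shape)
    cens = rng.uniform(*censor_range, n)
    events = (t_event <= cens).astype(int)
    times = np.minimum(t_event, cens)
    return values, times, events
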