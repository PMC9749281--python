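"""The 15 inflammation and nutrition indices.

Each index is registered once, keyed by its field name, with a group tag
(``inflammation`` or ``nutrition``) and a vectorized formula operating on
canonical-unit columns. The same formulas serve both the scalar per-patient
path (:func:`compute_index`) and the cohort path (:func:`compute_panel`),
so the two can never drift apart.

Inflammation group: LCR, CAR, NLR, SII, PLR, GLR, LCS, mGNRI, mGPS.
Nutrition group: ALI, PNI, NRI, GNRI, AGR, CONUT.

Formula conventions (all overridable through :class:`BiomarkerConfig`):

* LCR uses lymphocytes per microlitre over CRP in mg/dL — the scale on which
  the conventional prognostic cutpoints (thousands) live.
* NRI/GNRI/mGNRI cap the weight / ideal-weight ratio at 1, the standard
  geriatric-nutritional-risk-index convention; ideal weight is Lorentz.
* CONUT uses the original 0-12 scoring table (albumin, total lymphocyte
  count, total cholesterol).
* LCS awards one point for low lymphocytes and one for elevated CRP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .data_model import Cohort

__all__ = [
    "BiomarkerConfig",
    "DEFAULT_CONFIG",
    "INDEX_NAMES",
    "INDEX_GROUPS",
    "ideal_weight",
    "compute_index",
    "compute_panel",
]

MGDL_PER_MMOL_CHOLESTEROL = 38.67


@dataclass(frozen=True)
class BiomarkerConfig:
    """Tunable formula parameters (defaults are the literature conventions)."""

    lcs_lymphocyte_cutoff: float = 1.0   # 1e9/L; below scores 1
    lcs_crp_cutoff: float = 10.0         # mg/L; at/above scores 1
    mgps_crp_cutoff: float = 10.0        # mg/L
    mgps_albumin_cutoff: float = 35.0    # g/L
    cap_weight_ratio: bool = True        # min(1, weight/ideal) in NRI family


DEFAULT_CONFIG = BiomarkerConfig()


def ideal_weight(height: float | np.ndarray, sex) -> float | np.ndarray:
    """Lorentz ideal body weight (kg) from height (cm) and sex."""
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise ValueError("height must be positive")
    male = np.asarray(sex) == "male"
    out = np.where(
        male,
        height - 100.0 - (height - 150.0) / 4.0,
        height - 100.0 - (height - 150.0) / 2.5,
    )
    return float(out) if out.ndim == 0 else out


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def _weight_ratio(d: pd.DataFrame, cfg: BiomarkerConfig):
    r = _safe_div(d["weight"], ideal_weight(np.asarray(d["height"], float), d["sex"]))
    return np.minimum(r, 1.0) if cfg.cap_weight_ratio else r


def _nlr(d, cfg):
    return _safe_div(d["neutrophils"], d["lymphocytes"])


def _plr(d, cfg):
    return _safe_div(d["platelets"], d["lymphocytes"])


def _sii(d, cfg):
    return np.asarray(d["platelets"], float) * _nlr(d, cfg)


def _glr(d, cfg):
    return _safe_div(d["glucose"], d["lymphocytes"])


def _car(d, cfg):
    return _safe_div(d["crp"], d["albumin"])


def _lcr(d, cfg):
    # lymphocytes per uL over CRP in mg/dL: (lymph*1000) / (crp/10)
    return _safe_div(np.asarray(d["lymphocytes"], float) * 1e4, d["crp"])


def _mgps(d, cfg):
    crp = np.asarray(d["crp"], float)
    alb = np.asarray(d["albumin"], float)
    out = np.where(crp > cfg.mgps_crp_cutoff,
                   np.where(alb < cfg.mgps_albumin_cutoff, 2.0, 1.0), 0.0)
    return np.where(np.isnan(crp) | np.isnan(alb), np.nan, out)


def _lcs(d, cfg):
    lymph = np.asarray(d["lymphocytes"], float)
    crp = np.asarray(d["crp"], float)
    out = (lymph < cfg.lcs_lymphocyte_cutoff).astype(float) + (
        crp >= cfg.lcs_crp_cutoff
    ).astype(float)
    return np.where(np.isnan(lymph) | np.isnan(crp), np.nan, out)


def _ali(d, cfg):
    # BMI x albumin(g/dL) / NLR
    return _safe_div(np.asarray(d["bmi"], float) * np.asarray(d["albumin"], float) / 10.0,
                     _nlr(d, cfg))


def _pni(d, cfg):
    # 10 x albumin(g/dL) + 0.005 x lymphocytes per uL
    return (np.asarray(d["albumin"], float)
            + 0.005 * np.asarray(d["lymphocytes"], float) * 1000.0)


def _nri(d, cfg):
    return 1.519 * np.asarray(d["albumin"], float) + 41.7 * _weight_ratio(d, cfg)


def _gnri(d, cfg):
    return 1.489 * np.asarray(d["albumin"], float) + 41.7 * _weight_ratio(d, cfg)


def _mgnri(d, cfg):
    # CRP enters in mg/dL: 14.89 / crp(mg/dL) = 148.9 / crp(mg/L)
    return _safe_div(148.9, d["crp"]) + 41.7 * _weight_ratio(d, cfg)


def _agr(d, cfg):
    globulin = np.asarray(d["total_protein"], float) - np.asarray(d["albumin"], float)
    return _safe_div(d["albumin"], globulin)


def _conut(d, cfg):
    alb = np.asarray(d["albumin"], float) / 10.0  # g/dL
    lymph = np.asarray(d["lymphocytes"], float) * 1000.0  # per uL
    chol = np.asarray(d["cholesterol"], float) * MGDL_PER_MMOL_CHOLESTEROL  # mg/dL
    alb_s = np.select([alb >= 3.5, alb >= 3.0, alb >= 2.5], [0.0, 2.0, 4.0], 6.0)
    lym_s = np.select([lymph >= 1600, lymph >= 1200, lymph >= 800], [0.0, 1.0, 2.0], 3.0)
    cho_s = np.select([chol >= 180, chol >= 140, chol >= 100], [0.0, 1.0, 2.0], 3.0)
    out = alb_s + lym_s + cho_s
    return np.where(np.isnan(alb) | np.isnan(lymph) | np.isnan(chol), np.nan, out)


#: registry: index name -> (group, vectorized formula)
INDEX_REGISTRY: dict[str, tuple[str, Callable]] = {
    "LCR": ("inflammation", _lcr),
    "CAR": ("inflammation", _car),
    "NLR": ("inflammation", _nlr),
    "SII": ("inflammation", _sii),
    "PLR": ("inflammation", _plr),
    "GLR": ("inflammation", _glr),
    "LCS": ("inflammation", _lcs),
    "mGNRI": ("inflammation", _mgnri),
    "mGPS": ("inflammation", _mgps),
    "ALI": ("nutrition", _ali),
    "PNI": ("nutrition", _pni),
    "NRI": ("nutrition", _nri),
    "GNRI": ("nutrition", _gnri),
    "AGR": ("nutrition", _agr),
    "CONUT": ("nutrition", _conut),
}

INDEX_NAMES: tuple[str, ...] = tuple(INDEX_REGISTRY)
INDEX_GROUPS: dict[str, str] = {k: g for k, (g, _) in INDEX_REGISTRY.items()}

_NEEDED_COLS = (
    "lymphocytes", "neutrophils", "platelets", "crp", "albumin", "glucose",
    "total_protein", "cholesterol", "weight", "height", "bmi", "sex",
)


def _as_frame(record) -> pd.DataFrame:
    """Accept a PatientRecord, Series or mapping; return a 1-row frame."""
    if isinstance(record, pd.DataFrame):
        d = record.copy()
    elif isinstance(record, pd.Series):
        d = record.to_frame().T
    else:
        d = pd.DataFrame([{
            c: getattr(record, c, np.nan) for c in _NEEDED_COLS
        }])
    for c in _NEEDED_COLS:
        if c not in d.columns:
            if c == "bmi" and {"weight", "height"} <= set(d.columns):
                d["bmi"] = (np.asarray(d["weight"], float)
                            / (np.asarray(d["height"], float) / 100.0) ** 2)
            else:
                d[c] = np.nan
    return d


def compute_index(record, index_name: str,
                  config: BiomarkerConfig = DEFAULT_CONFIG) -> float:
    """Compute one named index for one patient; NaN when inputs are missing
    or a denominator is zero."""
    if index_name not in INDEX_REGISTRY:
        raise KeyError(
            f"unknown index {index_name!r}; known: {sorted(INDEX_REGISTRY)}"
        )
    _, fn = INDEX_REGISTRY[index_name]
    val = np.asarray(fn(_as_frame(record), config), dtype=float)
    return float(val.ravel()[0])


def compute_panel(cohort: Cohort | pd.DataFrame,
                  config: BiomarkerConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Compute the full n x 15 biomarker panel for a cohort.

    Missingness is per cell (an absent optional lab blanks only the indices
    that need it), and the computation is deterministic.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    d = _as_frame(df)
    out = pd.DataFrame(index=d.index)
    if "patient_id" in d.columns:
        out["patient_id"] = d["patient_id"].values
    for name, (_, fn) in INDEX_REGISTRY.items():
        out[name] = np.asarray(fn(d, config), dtype=float)
    return out
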