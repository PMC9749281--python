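"""The inflammation-nutrition score (INS).

Four biomarkers — LCR, CAR, ALI, NRI — are dichotomized at survival-optimal
thresholds; each adverse value scores one point, the points are summed, and
the sum plus one is the INS stratum (1-5). Stratum 1 means neither
inflammation nor nutrition risk; stratum 5 means both at their worst.

The scorer is generic over k components; the published 4-component instance
ships as :data:`INS_2022` with its thresholds bit-exact:
low LCR (< 2813), high CAR (>= 0.165), low ALI (< 33), low NRI (< 94).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerConfig, DEFAULT_CONFIG, compute_panel
from .data_model import Cohort

__all__ = ["Component", "INSConfig", "INS_2022", "INSResult",
           "dichotomize", "ins_score", "score_cohort"]

Direction = Literal["below", "at_or_above"]


@dataclass(frozen=True)
class Component:
    """One dichotomized score component: index name, threshold, adverse side."""

    index_name: str
    threshold: float
    direction: Direction

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise ValueError(f"threshold for {self.index_name} must be finite")
        if self.direction not in ("below", "at_or_above"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class INSConfig:
    """A named k-component scoring configuration (strata 1..k+1)."""

    components: tuple[Component, ...]
    name: str = "custom"

    def __post_init__(self):
        if len(self.components) == 0:
            raise ValueError("at least one component required")
        names = [c.index_name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component index names must be unique")

    @property
    def k(self) -> int:
        return len(self.components)

    @classmethod
    def from_mapping(cls, entries: Sequence[Mapping], name: str = "custom") -> "INSConfig":
        comps = tuple(
            Component(e["index_name"], float(e["threshold"]), e["direction"])
            for e in entries
        )
        return cls(comps, name=name)


#: the published default configuration
INS_2022 = INSConfig(
    components=(
        Component("LCR", 2813.0, "below"),
        Component("CAR", 0.165, "at_or_above"),
        Component("ALI", 33.0, "below"),
        Component("NRI", 94.0, "below"),
    ),
    name="INS-2022",
)


@dataclass(frozen=True)
class INSResult:
    """Per-patient score: adverse-indicator bits, raw score, stratum.

    ``stratum = raw_score + 1`` always; a missing component invalidates the
    whole score (``valid`` False) and the culprits are listed.
    """

    bits: dict[str, int]
    raw_score: int | None
    stratum: int | None
    valid: bool = True
    missing_components: tuple[str, ...] = ()


def dichotomize(value: float, threshold: float, direction: Direction) -> float:
    """1 if the value is on the adverse side of the threshold, else 0.

    ``below`` is strict (< threshold); ``at_or_above`` is inclusive
    (>= threshold). Missing in, missing out.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    value = np.asarray(value, dtype=float)
    if direction == "below":
        bit = (value < threshold).astype(float)
    elif direction == "at_or_above":
        bit = (value >= threshold).astype(float)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    out = np.where(np.isnan(value), np.nan, bit)
    return float(out) if out.ndim == 0 else out


def ins_score(panel, config: INSConfig = INS_2022) -> INSResult:
    """Score one patient's biomarker panel.

    ``panel`` maps index names to values (a dict, Series or BiomarkerPanel
    row). All components must be present; otherwise the result is invalid
    and lists the missing components.
    """
    getter = panel.get if hasattr(panel, "get") else panel.__getitem__
    bits: dict[str, int] = {}
    missing: list[str] = []
    for comp in config.components:
        raw = getter(comp.index_name)
        val = np.nan if raw is None else float(raw)
        if np.isnan(val):
            missing.append(comp.index_name)
            continue
        bits[comp.index_name] = int(dichotomize(val, comp.threshold, comp.direction))
    if missing:
        return INSResult(bits={}, raw_score=None, stratum=None, valid=False,
                         missing_components=tuple(missing))
    raw_score = sum(bits.values())
    return INSResult(bits=bits, raw_score=raw_score, stratum=raw_score + 1)


def score_cohort(
    cohort: Cohort,
    config: INSConfig = INS_2022,
    biomarker_config: BiomarkerConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.Series]:
    """Score every patient; returns (per-patient table, stratum frequencies).

    The table has one row per patient with the component bits, raw score,
    stratum and a ``valid`` flag; ineligible patients keep their row (with
    NaN score) rather than being silently dropped. The frequency table is
    indexed by stratum 1..k+1 and sums to the number of valid patients.
    """
    panel = compute_panel(cohort, biomarker_config)
    out = pd.DataFrame({"patient_id": cohort.data["patient_id"].values},
                       index=panel.index)
    bit_cols = []
    for comp in config.components:
        col = f"adverse_{comp.index_name}"
        out[col] = dichotomize(panel[comp.index_name].values,
                               comp.threshold, comp.direction)
        bit_cols.append(col)
    bits = out[bit_cols].to_numpy(dtype=float)
    valid = ~np.isnan(bits).any(axis=1)
    raw = np.where(valid, np.nansum(bits, axis=1), np.nan)
    out["raw_score"] = raw
    out["stratum"] = raw + 1.0
    out["valid"] = valid
    freq = (
        out.loc[valid, "stratum"].astype(int).value_counts()
        .reindex(range(1, config.k + 2), fill_value=0).sort_index()
    )
    freq.index.name = "stratum"
    return out, freq
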