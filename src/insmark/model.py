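"""Model/Results interface tying the whole INS workflow together.

:class:`INSModel` is constructed from a cohort (DataFrame, CSV or
:class:`~insmark.data_model.Cohort`); ``fit()`` runs validation, the
biomarker panel, optionally the data-driven construction stage (screening,
top-2-per-group selection, optimal cutpoints) and the evaluation battery,
returning an :class:`INSResults` carrying the scored table, hazard-ratio
tables, discrimination statistics and a ``summary()``.

Typical use::

    from insmark import INSModel
    from insmark.synthetic import simulate_cohort

    cohort, truth = simulate_cohort(seed=7)
    res = INSModel(cohort, horizon=36.0).fit(seed=7)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerConfig, DEFAULT_CONFIG, INDEX_GROUPS, compute_panel
from .cutpoints import optimal_cutpoint
from .data_model import Cohort, ValidationReport, read_cohort, validate_cohort
from .scoring import Component, INSConfig, INS_2022, score_cohort
from .survival_eval import (
    CoxSpec, EvalReport, cnri_idi, compare_c, cox_model, harrell_c,
    km_estimate, random_split, screen_biomarkers, select_top2_per_group,
    time_dependent_auc,
)

__all__ = ["INSModel", "INSResults"]


def _seed_offsets(seed: int | None) -> dict[str, int | None]:
    """Fan one run-level seed out to per-stage seeds by fixed offsets."""
    if seed is None:
        return {k: None for k in
                ("cutpoints", "c_boot", "delta_c", "nri", "lasso", "split")}
    return {"cutpoints": seed + 1, "c_boot": seed + 2, "delta_c": seed + 3,
            "nri": seed + 4, "lasso": seed + 5, "split": seed + 6}


def _component_risk(panel: pd.DataFrame, comp: Component) -> np.ndarray:
    """Orient a component index so that higher values mean higher risk."""
    v = panel[comp.index_name].to_numpy(float)
    return v if comp.direction == "at_or_above" else -v


class INSModel:
    """The inflammation-nutrition score model for one cohort.

    Parameters
    ----------
    data
        A :class:`Cohort` or a patient-level DataFrame in canonical units.
    score_config
        Scoring configuration; defaults to the published 4-component
        INS-2022 instance. Ignored when ``fit(select=True)`` re-derives the
        components and thresholds from this cohort.
    horizon
        Evaluation horizon in months for cNRI/IDI and AUC(t).
    biomarker_config
        Formula parameters for the index registry.
    """

    def __init__(self, data: Cohort | pd.DataFrame,
                 score_config: INSConfig = INS_2022,
                 horizon: float = 36.0,
                 biomarker_config: BiomarkerConfig = DEFAULT_CONFIG):
        self.cohort = data if isinstance(data, Cohort) else Cohort(
            data.copy(), provenance="dataframe")
        self.score_config = score_config
        self.horizon = float(horizon)
        self.biomarker_config = biomarker_config

    @classmethod
    def from_csv(cls, path, schema_config=None, **kwargs) -> "INSModel":
        return cls(read_cohort(path, schema_config), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "INSModel":
        return cls(df, **kwargs)

    # ------------------------------------------------------------------ fit

    def fit(self, seed: int | None = None, select: bool = False,
            use_lasso: bool = False, evaluate: bool = True,
            n_bootstrap: int = 200, adjusted: bool = True) -> "INSResults":
        """Run the pipeline and return results.

        ``select=True`` re-derives the four components from this cohort
        (concordance screen, top-2 per group, optimal cutpoints) instead of
        using the shipped configuration. ``adjusted`` controls whether the
        covariate-adjusted Cox model b is fitted alongside model a.
        """
        seeds = _seed_offsets(seed)
        validation = validate_cohort(self.cohort)
        panel = compute_panel(self.cohort, self.biomarker_config)
        df = self.cohort.data
        times = df["os_time"].to_numpy(float)
        events = df["event"].to_numpy(int)

        screen = None
        config = self.score_config
        if select:
            screen = screen_biomarkers(panel, times, events,
                                       use_lasso=use_lasso,
                                       seed=seeds["lasso"])
            chosen = select_top2_per_group(screen.c_table)
            comps = []
            for name in chosen:
                v = panel[name].to_numpy(float)
                m = ~np.isnan(v)
                cut = optimal_cutpoint(v[m], times[m], events[m])
                comps.append(Component(name, cut.threshold, cut.direction))
            config = INSConfig(tuple(comps), name="INS-refit")

        scored, freq = score_cohort(self.cohort, config, self.biomarker_config)

        report = None
        if evaluate:
            report = self._evaluate(panel, scored, times, events, config,
                                    seeds, n_bootstrap, adjusted)
        return INSResults(model=self, config=config, validation=validation,
                          panel=panel, scored=scored, stratum_freq=freq,
                          screen=screen, eval_report=report, seed=seed)

    def _evaluate(self, panel, scored, times, events, config, seeds,
                  n_bootstrap, adjusted) -> EvalReport:
        valid = scored["valid"].to_numpy()
        t, e = times[valid], events[valid]
        stratum = scored.loc[valid, "stratum"].to_numpy(float)

        ins_c = harrell_c(t, e, stratum, ci=True, n_bootstrap=n_bootstrap,
                          seed=seeds["c_boot"])
        c_stats = {"INS": {"c": ins_c.c, "ci": ins_c.ci}}
        delta_c, cnri_d, idi_d = {}, {}, {}
        for comp in config.components:
            risk = _component_risk(panel, comp)[valid]
            m = ~np.isnan(risk)
            cres = harrell_c(t[m], e[m], risk[m])
            c_stats[comp.index_name] = {"c": cres.c, "ci": None}
            dres = compare_c(t[m], e[m], risk[m], stratum[m],
                             n_bootstrap=n_bootstrap, seed=seeds["delta_c"])
            delta_c[comp.index_name] = {"delta": dres.delta, "p": dres.p_value,
                                        "ci": dres.ci}
            try:
                nri = cnri_idi(t[m], e[m], risk[m], stratum[m], self.horizon,
                               seed=seeds["nri"])
                cnri_d[comp.index_name] = {"value": nri.cnri, "ci": nri.cnri_ci}
                idi_d[comp.index_name] = {"value": nri.idi, "ci": nri.idi_ci}
            except ValueError as exc:
                warnings.warn(f"cNRI/IDI vs {comp.index_name} skipped: {exc}",
                              stacklevel=2)

        try:
            auc = {str(self.horizon):
                   time_dependent_auc(t, e, stratum, self.horizon)}
        except ValueError:
            auc = {}

        data_v = self.model_frame(scored)
        cox_a = cox_model(data_v, CoxSpec(adjustment="none"))
        cox_b = cox_model(data_v, CoxSpec(adjustment="model_b")) if adjusted else None
        return EvalReport(c_statistics=c_stats, delta_c=delta_c, cnri=cnri_d,
                          idi=idi_d, auc_t=auc, cox_model_a=cox_a,
                          cox_model_b=cox_b, horizon=self.horizon,
                          seed=seeds["c_boot"])

    def model_frame(self, scored: pd.DataFrame) -> pd.DataFrame:
        """Cohort covariates joined with the score, valid patients only."""
        df = self.cohort.data.copy()
        df["stratum"] = scored["stratum"].to_numpy()
        return df.loc[scored["valid"].to_numpy()].reset_index(drop=True)

    # ------------------------------------------------------------ validation

    def split_validate(self, ratio: float = 0.7, seed: int | None = None,
                       **fit_kwargs) -> dict[str, "INSResults"]:
        """Randomized internal validation: seeded split, re-evaluate per part."""
        seeds = _seed_offsets(seed)
        part_a, part_b = random_split(self.cohort, ratio, seeds["split"])
        out = {}
        for label, part in (("a", part_a), ("b", part_b)):
            sub = INSModel(part, score_config=self.score_config,
                           horizon=self.horizon,
                           biomarker_config=self.biomarker_config)
            out[label] = sub.fit(seed=seed, **fit_kwargs)
        return out


@dataclass
class INSResults:
    """Fitted results: scored cohort, configuration, diagnostics, report."""

    model: INSModel
    config: INSConfig
    validation: ValidationReport
    panel: pd.DataFrame
    scored: pd.DataFrame
    stratum_freq: pd.Series
    screen: object | None = None
    eval_report: EvalReport | None = None
    seed: int | None = None

    # death proportion per stratum (observed, not censoring-adjusted)
    def stratum_death_rates(self) -> pd.Series:
        df = self.model.cohort.data
        valid = self.scored["valid"].to_numpy()
        tab = pd.DataFrame({"stratum": self.scored.loc[valid, "stratum"].astype(int),
                            "event": df.loc[valid, "event"].to_numpy()})
        return tab.groupby("stratum")["event"].mean()

    def km_by_stratum(self) -> dict[int, object]:
        df = self.model.cohort.data
        valid = self.scored["valid"].to_numpy()
        out = {}
        for s in sorted(self.scored.loc[valid, "stratum"].astype(int).unique()):
            m = valid & (self.scored["stratum"] == s).to_numpy()
            out[s] = km_estimate(df.loc[m, "os_time"], df.loc[m, "event"])
        return out

    def summary(self) -> str:
        lines = [
            f"INS model results ({self.config.name}; "
            f"n={self.validation.n}, eligible={self.validation.eligible})",
            "=" * 64,
            "components:",
        ]
        for c in self.config.components:
            op = "<" if c.direction == "below" else ">="
            lines.append(f"  {c.index_name:>6} adverse if {op} {c.threshold:g}")
        lines.append("")
        lines.append("stratum  n       deaths")
        rates = self.stratum_death_rates()
        for s, n in self.stratum_freq.items():
            r = rates.get(s, np.nan)
            lines.append(f"  {s}      {n:<7d} {r:6.1%}" if np.isfinite(r)
                         else f"  {s}      {n:<7d}      -")
        if self.eval_report is not None:
            rep = self.eval_report
            lines.append("")
            for name, d in rep.c_statistics.items():
                ci = d.get("ci")
                ci_s = f"  (95% CI {ci[0]:.3f}-{ci[1]:.3f})" if ci else ""
                lines.append(f"C[{name:>5}] = {d['c']:.3f}{ci_s}")
            if rep.cox_model_a is not None:
                lines += ["", "Cox model a (unadjusted) hazard ratios:",
                          rep.cox_model_a.hr_table.to_string(
                              float_format=lambda v: f"{v:.3f}"),
                          f"P for trend: {rep.cox_model_a.p_trend:.3g}"]
            if rep.cox_model_b is not None:
                lines += ["", "Cox model b (adjusted) hazard ratios:",
                          rep.cox_model_b.hr_table.to_string(
                              float_format=lambda v: f"{v:.3f}"),
                          f"P for trend: {rep.cox_model_b.p_trend:.3g}"]
        return "\n".join(lines)

    def plot_km(self, ax=None):
        """Kaplan-Meier curves per stratum (matplotlib axes)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for s, km in self.km_by_stratum().items():
            ax.step(km.timeline, km.survival, where="post", label=f"INS {s}")
        ax.set_xlabel("months")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax
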