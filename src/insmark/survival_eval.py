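"""Survival evaluation battery for prognostic scores.

Implements the discrimination and association statistics used to judge a
prognostic biomarker or score against right-censored overall survival:

* Kaplan-Meier estimation and the two-group log-rank test (lifelines /
  :mod:`insmark.cutpoints`),
* Harrell's concordance index with bootstrap CIs, and paired comparisons
  of two scores on the same patients,
* continuous net reclassification improvement (cNRI) and integrated
  discrimination improvement (IDI) at a fixed horizon, censoring handled
  by inverse-probability-of-censoring weighting (IPCW),
* cumulative/dynamic time-dependent AUC with IPCW,
* Cox proportional-hazards models (unadjusted "model a" and covariate-
  adjusted "model b") with per-stratum hazard ratios and an ordinal-score
  trend test,
* restricted cubic spline (3 knots) dose-response with a Wald
  nonlinearity test,
* biomarker screening: univariable concordance ranking, Pearson
  collinearity matrix, and an L1-penalized Cox retained set with seeded
  cross-validated penalty selection,
* the top-2-per-group selection rule and the seeded 7:3 internal split.

Cox partial-likelihood fits and Kaplan-Meier estimation are delegated to
lifelines; the L1 path to scikit-survival. The reclassification statistics
and IPCW machinery are implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index
from scipy import stats

from .biomarkers import INDEX_GROUPS
from .data_model import Cohort

__all__ = [
    "KMEstimate", "CIndexResult", "DeltaCResult", "NriIdiResult",
    "CoxSpec", "CoxReport", "RCSResult", "ScreenResult", "EvalReport",
    "km_estimate", "harrell_c", "compare_c", "cnri_idi",
    "time_dependent_auc", "cox_model", "rcs_dose_response",
    "screen_biomarkers", "select_top2_per_group", "random_split",
]

MODEL_B_COVARIATES = (
    "age", "sex", "bmi", "tnm_stage", "tumor_type", "surgery", "radiotherapy",
    "chemotherapy", "hypertension", "diabetes", "smoking", "drinking",
    "family_history",
)


# ---------------------------------------------------------------- Kaplan-Meier

@dataclass
class KMEstimate:
    """Product-limit estimate: right-continuous step function, S(0) = 1."""

    timeline: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood

    def at(self, t, left: bool = False) -> np.ndarray | float:
        """S(t); with ``left=True`` the left limit S(t-)."""
        t = np.asarray(t, dtype=float)
        side = "left" if left else "right"
        idx = np.searchsorted(self.timeline, t, side=side) - 1
        s = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(s) if s.ndim == 0 else s


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator with Greenwood variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    # Greenwood variance on the same grid
    d = np.array([(events[(times == t)] == 1).sum() for t in timeline], float)
    n_at = np.array([(times >= t).sum() for t in timeline], float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where((n_at > 0) & (n_at > d), d / (n_at * (n_at - d)), 0.0)
    gw = surv ** 2 * np.cumsum(inc)
    return KMEstimate(timeline=timeline, survival=surv, variance=gw)


def _censoring_km(times, events) -> KMEstimate:
    """KM of the censoring distribution (event indicator flipped)."""
    return km_estimate(times, 1 - np.asarray(events, dtype=int))


# ------------------------------------------------------------- concordance

@dataclass(frozen=True)
class CIndexResult:
    c: float
    ci: tuple[float, float] | None = None


def harrell_c(times, events, risk, ci: bool = False,
              n_bootstrap: int = 200, seed: int | None = None) -> CIndexResult:
    """Harrell's C: concordant fraction of usable pairs, ties count half.

    A pair is usable iff the shorter observed time is an event; higher risk
    should predict shorter survival. CI (optional) by seeded bootstrap.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risk = np.asarray(risk, float)
    if len(times) < 2 or events.sum() == 0:
        raise ValueError("need at least 2 subjects and 1 event")
    # lifelines expects higher score = longer survival
    c = concordance_index(times, -risk, events)
    interval = None
    if ci:
        rng = np.random.default_rng(seed)
        n = len(times)
        boots = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            if events[idx].sum() == 0:
                continue
            boots.append(concordance_index(times[idx], -risk[idx], events[idx]))
        interval = tuple(np.percentile(boots, [2.5, 97.5]))
    return CIndexResult(c=float(c), ci=interval)


@dataclass(frozen=True)
class DeltaCResult:
    delta: float
    p_value: float
    ci: tuple[float, float]


def compare_c(times, events, risk_a, risk_b,
              n_bootstrap: int = 200, seed: int | None = None) -> DeltaCResult:
    """Paired difference in Harrell's C (b minus a); p by paired bootstrap."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risk_a = np.asarray(risk_a, float)
    risk_b = np.asarray(risk_b, float)
    if not (len(times) == len(risk_a) == len(risk_b)):
        raise ValueError("mismatched lengths")
    delta = (concordance_index(times, -risk_b, events)
             - concordance_index(times, -risk_a, events))
    rng = np.random.default_rng(seed)
    n = len(times)
    deltas = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        if events[idx].sum() == 0:
            continue
        deltas.append(concordance_index(times[idx], -risk_b[idx], events[idx])
                      - concordance_index(times[idx], -risk_a[idx], events[idx]))
    deltas = np.asarray(deltas)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    p = 2.0 * min((deltas <= 0).mean(), (deltas >= 0).mean())
    return DeltaCResult(delta=float(delta), p_value=float(min(1.0, p)),
                        ci=(float(lo), float(hi)))


# ------------------------------------------------- reclassification (IPCW)

def _risk_to_probability(times, events, risk, horizon: float,
                         mapping: str = "cox") -> np.ndarray:
    """Map a risk score to P(event by horizon).

    ``cox``: one-covariate Cox fit, baseline survival at the horizon.
    ``km_decile``: KM within risk deciles (fallback for non-monotone scores).
    """
    risk = np.asarray(risk, float)
    if mapping == "cox":
        scale = risk.std()
        z = (risk - risk.mean()) / (scale if scale > 0 else 1.0)
        df = pd.DataFrame({"t": times, "e": events, "z": z})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        s = cph.predict_survival_function(df[["z"]], times=[horizon])
        return 1.0 - s.iloc[0].to_numpy(dtype=float)
    if mapping == "km_decile":
        q = pd.qcut(pd.Series(risk).rank(method="first"), 10, labels=False)
        out = np.empty_like(risk)
        for g in np.unique(q):
            m = q == g
            out[np.asarray(m)] = 1.0 - km_estimate(
                np.asarray(times)[m], np.asarray(events)[m]).at(horizon)
        return out
    raise ValueError(f"unknown risk mapping {mapping!r}")


def _ipcw_status_weights(times, events, horizon: float):
    """Event status at the horizon with IPCW weights.

    Returns (is_event, is_nonevent, weights): subjects with an event by the
    horizon are weighted 1/G(T-); event-free past the horizon 1/G(horizon);
    censored before the horizon contribute zero weight.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    G = _censoring_km(times, events)
    is_event = (times <= horizon) & (events == 1)
    is_nonevent = times > horizon
    w = np.zeros_like(times)
    g_at_event = np.maximum(G.at(times[is_event], left=True), 1e-10)
    w[is_event] = 1.0 / g_at_event
    w[is_nonevent] = 1.0 / max(G.at(horizon), 1e-10)
    return is_event, is_nonevent, w


@dataclass(frozen=True)
class NriIdiResult:
    cnri: float
    idi: float
    cnri_ci: tuple[float, float] | None
    idi_ci: tuple[float, float] | None
    horizon: float
    estimator: str = "IPCW continuous NRI / IDI at fixed horizon"


def _cnri_idi_point(times, events, p_old, p_new, horizon):
    is_event, is_nonevent, w = _ipcw_status_weights(times, events, horizon)
    if not is_event.any():
        raise ValueError("no events by the horizon")
    up = p_new > p_old
    down = p_new < p_old
    we = w[is_event]
    wn = w[is_nonevent]
    if we.sum() == 0 or wn.sum() == 0:
        raise ValueError("degenerate weighting: empty event or non-event class")
    p_up_e = np.sum(we * up[is_event]) / we.sum()
    p_dn_e = np.sum(we * down[is_event]) / we.sum()
    p_up_n = np.sum(wn * up[is_nonevent]) / wn.sum()
    p_dn_n = np.sum(wn * down[is_nonevent]) / wn.sum()
    cnri = (p_up_e - p_dn_e) + (p_dn_n - p_up_n)
    d = p_new - p_old
    idi = (np.sum(we * d[is_event]) / we.sum()
           - np.sum(wn * d[is_nonevent]) / wn.sum())
    return float(cnri), float(idi)


def cnri_idi(times, events, risk_old, risk_new, horizon: float,
             mapping: str = "cox", ci: bool = False,
             n_bootstrap: int = 200, seed: int | None = None) -> NriIdiResult:
    """Continuous NRI and IDI of ``risk_new`` over ``risk_old`` at a horizon.

    Risks are mapped to predicted event probabilities at the horizon; event
    status at the horizon is IPCW-weighted by the censoring KM. The horizon
    must lie within follow-up support.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if horizon > times.max():
        raise ValueError("horizon beyond last observed time")
    p_old = _risk_to_probability(times, events, risk_old, horizon, mapping)
    p_new = _risk_to_probability(times, events, risk_new, horizon, mapping)
    cnri, idi = _cnri_idi_point(times, events, p_old, p_new, horizon)
    cnri_ci = idi_ci = None
    if ci:
        rng = np.random.default_rng(seed)
        n = len(times)
        cs, ds = [], []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            try:
                po = _risk_to_probability(times[idx], events[idx],
                                          np.asarray(risk_old)[idx], horizon, mapping)
                pn = _risk_to_probability(times[idx], events[idx],
                                          np.asarray(risk_new)[idx], horizon, mapping)
                c, d = _cnri_idi_point(times[idx], events[idx], po, pn, horizon)
            except Exception:
                continue
            cs.append(c)
            ds.append(d)
        if cs:
            cnri_ci = tuple(np.percentile(cs, [2.5, 97.5]))
            idi_ci = tuple(np.percentile(ds, [2.5, 97.5]))
    return NriIdiResult(cnri=cnri, idi=idi, cnri_ci=cnri_ci, idi_ci=idi_ci,
                        horizon=horizon)


def time_dependent_auc(times, events, risk, t: float) -> float:
    """Cumulative/dynamic AUC(t) with IPCW: probability that a subject with
    an event by t carries higher risk than one event-free past t."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risk = np.asarray(risk, float)
    is_case, is_control, w = _ipcw_status_weights(times, events, t)
    if not is_case.any() or not is_control.any():
        raise ValueError("need both cases and controls at t")
    rc, wc = risk[is_case], w[is_case]
    rk, wk = risk[is_control], w[is_control]
    comp = (rc[:, None] > rk[None, :]) + 0.5 * (rc[:, None] == rk[None, :])
    num = float(np.sum(wc[:, None] * wk[None, :] * comp))
    den = float(wc.sum() * wk.sum())
    return num / den


# ------------------------------------------------------------------- Cox

@dataclass(frozen=True)
class CoxSpec:
    """Exposure and adjustment set for the association models.

    ``adjustment='none'`` is the unadjusted model a; ``'model_b'`` adjusts
    for age, sex, BMI, TNM stage, tumor type, treatments, comorbidities,
    smoking, drinking and family history.
    """

    exposure: str = "stratum"
    exposure_type: Literal["categorical", "continuous"] = "categorical"
    reference: float = 1
    adjustment: str | Sequence[str] = "none"

    def covariates(self) -> tuple[str, ...]:
        if self.adjustment == "none":
            return ()
        if self.adjustment == "model_b":
            return MODEL_B_COVARIATES
        return tuple(self.adjustment)


@dataclass
class CoxReport:
    """Hazard-ratio table per exposure level plus the ordinal trend test."""

    hr_table: pd.DataFrame  # index: exposure level; HR, ci_low, ci_high, p
    p_trend: float
    n: int
    n_events: int
    model: str = "model_a"

    def to_markdown(self) -> str:
        lines = [f"Cox {self.model} (n={self.n}, events={self.n_events})",
                 self.hr_table.to_string(float_format=lambda v: f"{v:.3f}"),
                 f"P for trend: {self.p_trend:.3g}"]
        return "\n".join(lines)


def _design_frame(data: pd.DataFrame, spec: CoxSpec) -> pd.DataFrame:
    df = pd.DataFrame({"os_time": data["os_time"].to_numpy(float),
                       "event": data["event"].to_numpy(int)})
    for cov in spec.covariates():
        col = data[cov]
        if col.dtype == bool:
            df[cov] = col.astype(float).to_numpy()
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                df[c] = dummies[c].to_numpy()
        else:
            df[cov] = col.to_numpy(float)
    return df


def cox_model(data: pd.DataFrame, spec: CoxSpec = CoxSpec()) -> CoxReport:
    """Cox proportional-hazards HRs per exposure stratum vs the reference.

    ``data`` needs ``os_time``, ``event``, the exposure column and any
    adjustment covariates. The trend p comes from a second fit with the
    exposure entered as a single continuous ordinal term.
    """
    exp = data[spec.exposure]
    if exp.nunique() < 2:
        raise ValueError("constant exposure")
    df = _design_frame(data, spec)
    n_events = int(df["event"].sum())

    levels = sorted(exp.unique())
    exp_cols = []
    for lv in levels:
        if lv == spec.reference:
            continue
        c = f"{spec.exposure}_{lv}"
        df[c] = (exp == lv).astype(float).to_numpy()
        exp_cols.append((lv, c))
    n_params = df.shape[1] - 2
    if n_events < 10 * n_params:
        warnings.warn(
            f"only {n_events} events for {n_params} parameters "
            "(below 10 events per parameter)", stacklevel=2)

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise ValueError(
            f"Cox fit failed (possible separation / monotone likelihood): {exc}"
        ) from exc

    rows = [{"level": spec.reference, "HR": 1.0, "ci_low": np.nan,
             "ci_high": np.nan, "p": np.nan}]
    ci = cph.confidence_intervals_
    for lv, c in exp_cols:
        rows.append({
            "level": lv,
            "HR": float(np.exp(cph.params_[c])),
            "ci_low": float(np.exp(ci.loc[c].iloc[0])),
            "ci_high": float(np.exp(ci.loc[c].iloc[1])),
            "p": float(cph.summary.loc[c, "p"]),
        })
    hr_table = pd.DataFrame(rows).set_index("level")

    # ordinal-score trend test: exposure as one continuous term
    df_tr = df.drop(columns=[c for _, c in exp_cols])
    df_tr["trend"] = pd.to_numeric(exp, errors="coerce").to_numpy(float)
    cph_tr = CoxPHFitter()
    cph_tr.fit(df_tr, duration_col="os_time", event_col="event")
    p_trend = float(cph_tr.summary.loc["trend", "p"])

    model = "model_b" if spec.adjustment == "model_b" else (
        "model_a" if spec.adjustment == "none" else "custom")
    return CoxReport(hr_table=hr_table, p_trend=p_trend, n=len(df),
                     n_events=n_events, model=model)


# ------------------------------------------------------- restricted splines

def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (k knots -> k-1 columns, linear tails).

    Column 0 is x itself; the nonlinear columns use the standard truncated
    power basis normalized by (t_k - t_1)^2.
    """
    x = np.asarray(x, float)
    knots = np.asarray(knots, float)
    k = len(knots)
    if k < 3:
        raise ValueError("need at least 3 knots")
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    norm = (tk - t1) ** 2

    def pos3(u):
        return np.clip(u, 0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        col = (pos3(x - tj)
               - pos3(x - tk1) * (tk - tj) / (tk - tk1)
               + pos3(x - tk) * (tk1 - tj) / (tk - tk1)) / norm
        cols.append(col)
    return np.column_stack(cols)


@dataclass
class RCSResult:
    """Spline dose-response: log-HR curve vs the median, nonlinearity Wald p."""

    grid: np.ndarray
    log_hr: np.ndarray
    knots: np.ndarray
    p_nonlinear: float
    basis_columns: int


def rcs_dose_response(x, times, events,
                      knots: Sequence[float] | None = None,
                      n_grid: int = 100) -> RCSResult:
    """Cox dose-response with a restricted cubic spline (default 3 knots at
    the 0.10/0.50/0.90 quantiles); curve referenced to the median of x."""
    x = np.asarray(x, float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values")
    if knots is None:
        knots = np.quantile(x, [0.10, 0.50, 0.90])
    knots = np.asarray(knots, float)
    B = rcs_basis(x, knots)
    ncols = B.shape[1]
    df = pd.DataFrame(B, columns=[f"s{j}" for j in range(ncols)])
    df["os_time"] = np.asarray(times, float)
    df["event"] = np.asarray(events, int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="os_time", event_col="event")

    beta = cph.params_.to_numpy()
    cov = cph.variance_matrix_.to_numpy()
    b_nl = beta[1:ncols]  # nonlinear terms
    v_nl = cov[1:ncols, 1:ncols]
    chi2 = float(b_nl @ np.linalg.solve(v_nl, b_nl))
    p_nonlinear = float(stats.chi2.sf(chi2, df=ncols - 1))

    grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), n_grid)
    Bg = rcs_basis(grid, knots)
    Bref = rcs_basis(np.array([np.median(x)]), knots)
    log_hr = (Bg - Bref) @ beta
    return RCSResult(grid=grid, log_hr=log_hr, knots=knots,
                     p_nonlinear=p_nonlinear, basis_columns=ncols)


# ----------------------------------------------------------- screening

@dataclass
class ScreenResult:
    """Univariable C ranking, Pearson matrix and LASSO-retained biomarkers."""

    c_table: pd.DataFrame        # index, group, c, direction
    correlation: pd.DataFrame    # Pearson, pairwise-complete
    lasso_retained: tuple[str, ...]


def screen_biomarkers(panel: pd.DataFrame, times, events,
                      groups: dict[str, str] | None = None,
                      use_lasso: bool = True, n_folds: int = 5,
                      seed: int | None = None) -> ScreenResult:
    """Rank biomarkers by univariable concordance and screen collinearity.

    Concordance is orientation-free (reported as max(c, 1-c), with the
    adverse direction recorded), mirroring how prognostic indices are
    conventionally reported. All-missing columns are dropped with a warning.
    The L1-penalized Cox retained set uses a seeded cross-validated penalty.
    """
    groups = groups or INDEX_GROUPS
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    cols = [c for c in panel.columns if c != "patient_id"]
    usable = []
    for c in cols:
        if panel[c].notna().sum() == 0:
            warnings.warn(f"biomarker {c} is entirely missing; excluded",
                          stacklevel=2)
        else:
            usable.append(c)
    if len(usable) < 2 or events.sum() < 20:
        raise ValueError("need at least 2 biomarkers and 20 events")

    rows = []
    for c in usable:
        v = panel[c].to_numpy(float)
        m = ~np.isnan(v)
        c_raw = harrell_c(times[m], events[m], v[m]).c
        oriented = max(c_raw, 1.0 - c_raw)
        rows.append({"index": c, "group": groups.get(c, "unknown"),
                     "c": oriented,
                     "direction": "at_or_above" if c_raw >= 0.5 else "below"})
    c_table = pd.DataFrame(rows).set_index("index")

    corr = panel[usable].corr(method="pearson")

    retained: tuple[str, ...] = ()
    if use_lasso:
        retained = _lasso_cox_retained(panel[usable], times, events,
                                       n_folds=n_folds, seed=seed)
    return ScreenResult(c_table=c_table, correlation=corr,
                        lasso_retained=retained)


def _lasso_cox_retained(X: pd.DataFrame, times, events,
                        n_folds: int = 5, seed: int | None = None
                        ) -> tuple[str, ...]:
    """L1 Cox path (scikit-survival coxnet); penalty by seeded k-fold CV
    scored with held-out concordance."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    mask = ~X.isna().any(axis=1).to_numpy()
    Xc = X.loc[mask]
    t, e = np.asarray(times)[mask], np.asarray(events)[mask].astype(bool)
    Xs = (Xc - Xc.mean()) / Xc.std().replace(0, 1.0)
    y = Surv.from_arrays(event=e, time=t)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=30)
    path.fit(Xs.to_numpy(), y)
    alphas = path.alphas_

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(Xs))
    folds = np.array_split(idx, n_folds)
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for f in folds:
        train = np.setdiff1d(idx, f)
        if e[f].sum() == 0 or e[train].sum() == 0:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        try:
            m.fit(Xs.to_numpy()[train], y[train])
        except Exception:
            continue
        for i, a in enumerate(alphas):
            try:
                pred = m.predict(Xs.to_numpy()[f], alpha=a)
            except Exception:
                continue
            if np.ptp(pred) == 0:
                continue
            scores[i] += concordance_index(t[f], -pred, e[f])
            counts[i] += 1
    valid = counts > 0
    if not valid.any():
        best_alpha = alphas[len(alphas) // 2]
    else:
        mean_scores = np.where(valid, scores / np.maximum(counts, 1), -np.inf)
        best_alpha = alphas[int(np.argmax(mean_scores))]
    coef = pd.Series(
        path.coef_[:, int(np.argmin(np.abs(path.alphas_ - best_alpha)))],
        index=Xs.columns,
    )
    return tuple(coef.index[coef.abs() > 1e-10])


def select_top2_per_group(c_table: pd.DataFrame,
                          registry_order: Sequence[str] | None = None
                          ) -> tuple[str, ...]:
    """Pick the two highest-concordance biomarkers from the inflammation
    group and two from the nutrition group; ties break by registry order."""
    order = list(registry_order or INDEX_GROUPS)
    selected: list[str] = []
    for grp in ("inflammation", "nutrition"):
        sub = c_table[c_table["group"] == grp]
        if len(sub) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 usable biomarkers")
        ranked = sorted(sub.index,
                        key=lambda i: (-sub.loc[i, "c"], order.index(i)
                                       if i in order else len(order)))
        if len(sub) > 2 and sub["c"].nunique() == 1:
            warnings.warn(f"all concordances tied in group {grp!r}; "
                          "selection falls back to registry order", stacklevel=2)
        selected.extend(ranked[:2])
    return tuple(selected)


def random_split(cohort: Cohort, ratio: float = 0.7,
                 seed: int | None = None) -> tuple[Cohort, Cohort]:
    """Seeded disjoint exhaustive partition; |a| = round(ratio * n)."""
    n = len(cohort)
    if n < 10:
        raise ValueError("need at least 10 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_a = int(round(ratio * n))
    a = cohort.data.iloc[np.sort(perm[:n_a])].reset_index(drop=True)
    b = cohort.data.iloc[np.sort(perm[n_a:])].reset_index(drop=True)
    return (Cohort(a, provenance=f"{cohort.provenance}[split-a seed={seed}]"),
            Cohort(b, provenance=f"{cohort.provenance}[split-b seed={seed}]"))


# ----------------------------------------------------------------- report

@dataclass
class EvalReport:
    """Discrimination metrics and Cox HR tables for a scored cohort."""

    c_statistics: dict[str, dict]          # model -> {c, ci}
    delta_c: dict[str, dict]               # comparator -> {delta, p, ci}
    cnri: dict[str, dict]
    idi: dict[str, dict]
    auc_t: dict[str, float]                # "t" -> AUC(t)
    cox_model_a: CoxReport | None = None
    cox_model_b: CoxReport | None = None
    horizon: float = 36.0
    estimator_notes: str = ("cNRI/IDI: IPCW at fixed horizon; risk mapped to "
                            "event probability via one-covariate Cox baseline")
    seed: int | None = None

    def to_json(self) -> str:
        def cox(o):
            if o is None:
                return None
            return {"hr_table": o.hr_table.reset_index().to_dict("records"),
                    "p_trend": o.p_trend, "n": o.n,
                    "n_events": o.n_events, "model": o.model}

        payload = {
            "c_statistics": self.c_statistics, "delta_c": self.delta_c,
            "cnri": self.cnri, "idi": self.idi, "auc_t": self.auc_t,
            "cox_model_a": cox(self.cox_model_a),
            "cox_model_b": cox(self.cox_model_b),
            "horizon": self.horizon, "estimator_notes": self.estimator_notes,
            "seed": self.seed,
        }

        def enc(o):
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            if isinstance(o, (np.ndarray, tuple)):
                return list(o)
            raise TypeError(type(o))
        return json.dumps(payload, default=enc, indent=2)

    def to_markdown(self) -> str:
        lines = ["# Evaluation report", "",
                 f"Horizon: {self.horizon} months. {self.estimator_notes}.", "",
                 "## Discrimination (Harrell's C)"]
        for model, d in self.c_statistics.items():
            ci = d.get("ci")
            ci_s = f" ({ci[0]:.3f}, {ci[1]:.3f})" if ci else ""
            lines.append(f"- {model}: C = {d['c']:.3f}{ci_s}")
        if self.delta_c:
            lines += ["", "## Incremental value vs comparators",
                      "| comparator | dC | p | cNRI | IDI |",
                      "|---|---|---|---|---|"]
            for name in self.delta_c:
                dc = self.delta_c[name]
                cn = self.cnri.get(name, {})
                di = self.idi.get(name, {})
                lines.append(
                    f"| {name} | {dc['delta']:+.3f} | {dc['p']:.3g} "
                    f"| {cn.get('value', float('nan')):+.3f} "
                    f"| {di.get('value', float('nan')):+.3f} |")
        for rep, label in ((self.cox_model_a, "Model a (unadjusted)"),
                           (self.cox_model_b, "Model b (adjusted)")):
            if rep is not None:
                lines += ["", f"## Cox {label}", "",
                          rep.hr_table.to_markdown() if hasattr(rep.hr_table, "to_markdown")
                          else rep.hr_table.to_string(),
                          f"", f"P for trend: {rep.p_trend:.3g}"]
        return "\n".join(lines)
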