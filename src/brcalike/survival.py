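"""Survival endpoints, Kaplan-Meier summaries, and Cox interaction models.

Endpoints follow the usual adjuvant-trial conventions: recurrence-free
survival (RFS) runs from randomization to invasive recurrence, death from
any cause, or last follow-up, whichever is first; overall survival (OS)
counts death from any cause only.  Median follow-up is the median of the
reverse Kaplan-Meier estimator (censoring treated as the event).

The Cox proportional-hazards fitter maximizes the log partial likelihood by
Newton-Raphson with either the Efron (default) or Breslow ties correction,
to a gradient max-norm below 1e-8.  The predictive-biomarker question is
asked through a treatment x marker interaction model: within-stratum
treatment hazard ratios are linear combinations of its coefficients, and
the interaction Wald test compares them.  Proportionality is checked with
scaled Schoenfeld residuals against event time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ARM_CAPECITABINE, ARM_CONTROL, BRCA1_LIKE, NON_BRCA1_LIKE

Z_95 = 1.96  # Wald 95% CI multiplier


# ---------------------------------------------------------------------------
# endpoints
# ---------------------------------------------------------------------------

def derive_endpoints(records: pd.DataFrame) -> pd.DataFrame:
    """Derive RFS and OS per patient from raw event and follow-up times.

    Adds rfs_time, rfs_event, os_time, os_event (times in years).  An event
    time recorded after the end of follow-up is inconsistent and rejected.
    """
    rec = records["time_to_recurrence"].to_numpy(dtype=float)
    death = records["time_to_death"].to_numpy(dtype=float)
    fup = records["followup_time"].to_numpy(dtype=float)
    if (fup <= 0).any():
        raise ValueError("followup_time must be positive")
    for name, t in (("time_to_recurrence", rec), ("time_to_death", death)):
        bad = np.flatnonzero(~np.isnan(t) & (t > fup))
        if len(bad):
            raise ValueError(f"{name} after end of follow-up for row(s) {bad.tolist()}")

    event_min = np.fmin(rec, death)  # NaN-ignoring min
    rfs_event = (~np.isnan(event_min)).astype(int)
    rfs_time = np.where(rfs_event == 1, event_min, fup)
    os_event = (~np.isnan(death)).astype(int)
    os_time = np.where(os_event == 1, death, fup)

    out = records.copy()
    out["rfs_time"], out["rfs_event"] = rfs_time, rfs_event
    out["os_time"], out["os_event"] = os_time, os_event
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(time, event, risk_times=None):
    """Product-limit survival estimate plus an at-risk table.

    Returns (curve, risk_table): `curve` has columns time, survival,
    n_at_risk, n_events (one row per distinct event time, prepended with
    t=0); `risk_table` lists patients still at risk at each requested time.
    """
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) < 1:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    curve = pd.DataFrame({
        "time": table.index.to_numpy(dtype=float),
        "survival": surv.reindex(table.index).to_numpy(dtype=float),
        "n_at_risk": table["at_risk"].to_numpy(dtype=int),
        "n_events": table["observed"].to_numpy(dtype=int),
    })
    risk_table = None
    if risk_times is not None:
        risk_table = pd.DataFrame({
            "time": list(risk_times),
            "n_at_risk": [int((time >= t).sum()) for t in risk_times],
            "survival": [float(kmf.predict(t)) for t in risk_times],
        })
    return curve, risk_table


def reverse_km_median_followup(time, event) -> float:
    """Median follow-up by the reverse Kaplan-Meier estimator.

    The event/censoring indicators are flipped (censoring becomes the event)
    and the first time the flipped curve reaches <= 0.5 is returned;
    `math.inf` means the median follow-up was not reached.
    """
    event = np.asarray(event, dtype=int)
    curve, _ = km_estimate(time, 1 - event)
    below = curve[curve["survival"] <= 0.5 + 1e-12]
    if below.empty:
        return math.inf
    return float(below["time"].iloc[0])


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    terms: list
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    ties: str
    cov: np.ndarray = field(repr=False, default=None)
    n: int = 0
    n_events: int = 0

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - Z_95 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + Z_95 * self.se)

    @property
    def p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "coef": self.coef, "se": self.se,
            "hr": self.hr, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "p": self.p,
        })


def _cox_quantities(beta, t, d, X, ties, want_resid=False):
    """Log partial likelihood, gradient, Hessian (and Schoenfeld residuals).

    Assumes rows sorted by ascending time.  `ties` is "efron" or "breslow".
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; PL is invariant to the shift
    r = np.exp(eta)
    rx = r[:, None] * X
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rx[::-1], axis=0)[::-1]
    rxx = rx[:, :, None] * X[:, None, :]
    S2 = np.cumsum(rxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    resid, resid_times = [], []

    _, group_starts = np.unique(t, return_index=True)
    group_starts = np.append(group_starts, n)
    for gi in range(len(group_starts) - 1):
        i, j = group_starts[gi], group_starts[gi + 1]
        ev = np.flatnonzero(d[i:j]) + i
        D = len(ev)
        if D == 0:
            continue
        s0, s1, s2 = S0[i], S1[i], S2[i]
        rd = r[ev]
        s0d = rd.sum()
        s1d = rx[ev].sum(axis=0)
        s2d = rxx[ev].sum(axis=0)
        loglik += eta[ev].sum()
        grad += X[ev].sum(axis=0)
        xbar_acc = np.zeros(p)
        for el in range(D):
            phi = el / D if ties == "efron" else 0.0
            den = s0 - phi * s0d
            num = s1 - phi * s1d
            m2 = s2 - phi * s2d
            loglik -= math.log(den)
            xbar = num / den
            grad -= xbar
            info += m2 / den - np.outer(xbar, xbar)
            xbar_acc += xbar
        if want_resid:
            xbar_mean = xbar_acc / D
            for k in ev:
                resid.append(X[k] - xbar_mean)
                resid_times.append(t[k])
    if want_resid:
        return loglik, grad, info, np.asarray(resid), np.asarray(resid_times)
    return loglik, grad, info


def _split_strata(time, event, X, strata):
    """Sort within strata; returns a list of (t, d, X) blocks."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    blocks = []
    if strata is None:
        groups = [np.arange(len(time))]
    else:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
    for idx in groups:
        order = idx[np.argsort(time[idx], kind="mergesort")]
        blocks.append((time[order], event[order], X[order]))
    return blocks


def _strata_quantities(beta, blocks, ties):
    ll = 0.0
    g = np.zeros(len(beta))
    info = np.zeros((len(beta), len(beta)))
    for t, d, Xs in blocks:
        if d.sum() == 0:
            continue
        bll, bg, binfo = _cox_quantities(beta, t, d, Xs, ties)
        ll += bll
        g += bg
        info += binfo
    return ll, g, info


def fit_cox(time, event, X, terms=None, ties: str = "efron", strata=None,
            max_iter: int = 100, grad_tol: float = 1e-8) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    X is the design matrix (n x p, numeric); `ties` selects the Efron or
    Breslow partial-likelihood correction; `strata` (optional labels per
    subject) gives each stratum its own baseline hazard, with shared
    coefficients.  Convergence requires the gradient max-norm below
    `grad_tol`; non-convergence or separation-like coefficient divergence
    raises with a diagnostic.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if isinstance(X, pd.DataFrame):
        terms = terms or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and len(np.asarray(time)) > 1:
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    terms = terms or [f"x{i}" for i in range(p)]
    if event.sum() < 1:
        raise ValueError("need at least one event")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise ValueError(f"constant term(s) in design: {[terms[i] for i in np.flatnonzero(const)]}")

    blocks = _split_strata(time, event, X, strata)
    beta = np.zeros(p)
    ll, g, info = _strata_quantities(beta, blocks, ties)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < grad_tol:
            break
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix in Cox fit") from exc
        accepted = False
        for _ in range(40):
            cand = beta + step
            cll, cg, cinfo = _strata_quantities(cand, blocks, ties)
            if np.isfinite(cll) and cll >= ll - 1e-10 * (1.0 + abs(ll)):
                beta, ll, g, info = cand, cll, cg, cinfo
                accepted = True
                break
            step /= 2.0
        if not accepted or np.max(np.abs(beta)) > 30:
            raise RuntimeError(
                "Cox fit failed to converge (possible complete separation); "
                f"max |coef| = {np.max(np.abs(beta)):.3g}"
            )
    else:
        raise RuntimeError(
            f"Cox fit did not reach gradient tolerance {grad_tol:g} in {max_iter} iterations"
        )
    cov = np.linalg.inv(info)
    return CoxFit(terms=terms, coef=beta, se=np.sqrt(np.diag(cov)), loglik=ll,
                  ties=ties, cov=cov, n=n, n_events=int(event.sum()))


def cox_loglik(beta, time, event, X, ties: str = "breslow") -> float:
    """Log partial likelihood at an arbitrary coefficient vector (for audits)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(np.asarray(time)) > 1:
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="mergesort")
    ll, _, _ = _cox_quantities(np.atleast_1d(np.asarray(beta, dtype=float)),
                               time[order], event[order], X[order], ties)
    return ll


# ---------------------------------------------------------------------------
# interaction analysis
# ---------------------------------------------------------------------------

def _dummy_code(series: pd.Series, name: str):
    """Dummy-code a covariate against its first listed level (sorted for
    strings unless a categorical ordering is supplied); numeric columns pass
    through unchanged."""
    if pd.api.types.is_numeric_dtype(series):
        return pd.DataFrame({name: series.to_numpy(dtype=float)})
    if isinstance(series.dtype, pd.CategoricalDtype):
        levels = list(series.cat.categories)
    else:
        levels = sorted(pd.unique(series.astype(str)))
    ref = levels[0]
    cols = {}
    for lev in levels[1:]:
        cols[f"{name}[{lev}]"] = (series.astype(str) == lev).astype(float).to_numpy()
    if not cols:
        raise ValueError(f"covariate {name!r} has a single level ({ref!r})")
    return pd.DataFrame(cols)


@dataclass
class InteractionResult:
    endpoint: str
    fit: CoxFit
    hr_treatment_marker_neg: float
    ci_treatment_marker_neg: tuple
    hr_treatment_marker_pos: float
    ci_treatment_marker_pos: tuple
    interaction_coef: float
    interaction_se: float
    interaction_p: float
    cell_table: pd.DataFrame
    adjusted_for: str | None = None

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "adjusted_for": self.adjusted_for,
            "hr_treatment_marker_neg": self.hr_treatment_marker_neg,
            "ci_treatment_marker_neg": list(self.ci_treatment_marker_neg),
            "hr_treatment_marker_pos": self.hr_treatment_marker_pos,
            "ci_treatment_marker_pos": list(self.ci_treatment_marker_pos),
            "interaction_coef": self.interaction_coef,
            "interaction_p": self.interaction_p,
            "cell_table": self.cell_table.to_dict("records"),
            "model": self.fit.summary().to_dict("records"),
        }


def interaction_analysis(
    records: pd.DataFrame,
    endpoint: str = "rfs",
    adjust_for: str | None = None,
    ties: str = "efron",
    treatment_arm: str = ARM_CAPECITABINE,
    marker_positive: str = BRCA1_LIKE,
) -> InteractionResult:
    """Cox interaction model: treatment + treatment x marker, with the
    baseline hazard stratified by marker status.

    Stratifying the baseline makes the within-stratum treatment hazard
    ratios exact reparameterizations — exp(b_treatment) equals the Cox fit
    restricted to marker-negative patients, exp(b_treatment + b_interaction)
    the marker-positive one — while the interaction Wald test compares them.
    (The marker's own prognostic HR, absorbed here by the stratified
    baselines, comes from a separate unstratified fit.)  All four arm x
    marker cells must be non-empty; adjustment is deliberately one covariate
    at a time.
    """
    if endpoint not in ("rfs", "os"):
        raise ValueError("endpoint must be 'rfs' or 'os'")
    if f"{endpoint}_time" not in records.columns:
        records = derive_endpoints(records)
    treat = (records["arm"] == treatment_arm).astype(float).to_numpy()
    marker = (records["marker"] == marker_positive).astype(float).to_numpy()
    cells = records.groupby(
        [records["marker"], records["arm"]], observed=True
    )[f"{endpoint}_event"].agg(["sum", "size"])
    if len(cells) < 4:
        raise ValueError("all four arm x marker cells must be non-empty")

    design = pd.DataFrame({
        "treatment": treat,
        "treatment:marker": treat * marker,
    })
    if adjust_for is not None:
        design = pd.concat([design, _dummy_code(records[adjust_for], adjust_for)], axis=1)

    fit = fit_cox(records[f"{endpoint}_time"], records[f"{endpoint}_event"], design,
                  ties=ties, strata=marker)
    bt = fit.coef[0]
    bi = fit.coef[1]
    var_t = fit.cov[0, 0]
    var_sum = fit.cov[0, 0] + fit.cov[1, 1] + 2.0 * fit.cov[0, 1]
    se_sum = math.sqrt(var_sum)
    hr_neg = math.exp(bt)
    hr_pos = math.exp(bt + bi)

    cell_table = (
        cells.rename(columns={"sum": "events", "size": "n"})
        .reset_index()
        .rename(columns={"level_0": "marker", "level_1": "arm"})
    )
    cell_table["events"] = cell_table["events"].astype(int)

    se_t = math.sqrt(var_t)
    return InteractionResult(
        endpoint=endpoint,
        fit=fit,
        hr_treatment_marker_neg=hr_neg,
        ci_treatment_marker_neg=(hr_neg * math.exp(-Z_95 * se_t), hr_neg * math.exp(Z_95 * se_t)),
        hr_treatment_marker_pos=hr_pos,
        ci_treatment_marker_pos=(hr_pos * math.exp(-Z_95 * se_sum), hr_pos * math.exp(Z_95 * se_sum)),
        interaction_coef=bi,
        interaction_se=fit.se[1],
        interaction_p=float(2.0 * stats.norm.sf(abs(bi / fit.se[1]))),
        cell_table=cell_table,
        adjusted_for=adjust_for,
    )


def adjusted_interaction_pvalues(records: pd.DataFrame, endpoint: str = "rfs",
                                 covariates=None, ties: str = "efron") -> pd.Series:
    """Interaction p-values adjusted for one covariate at a time.

    Returns a Series indexed by covariate name (None key = unadjusted);
    mirrors the small-events practice of never adjusting for everything at
    once.
    """
    covariates = covariates or ["age", "who_ps", "surgery", "axillary_surgery",
                                "t_stage", "nodes", "histology", "grade"]
    out = {"unadjusted": interaction_analysis(records, endpoint, None, ties).interaction_p}
    for cov in covariates:
        out[cov] = interaction_analysis(records, endpoint, cov, ties).interaction_p
    return pd.Series(out, name=f"{endpoint}_interaction_p")


# ---------------------------------------------------------------------------
# Schoenfeld proportionality check
# ---------------------------------------------------------------------------

def schoenfeld_check(fit: CoxFit, time, event, X, strata=None) -> pd.DataFrame:
    """Proportional-hazards check via scaled Schoenfeld residuals.

    Correlates the scaled residuals with event time (identity transform) and
    returns a per-term chi-square statistic and p-value; a small p flags a
    time-varying effect.  Needs at least two events.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if X.shape[0] == 1 and len(time) > 1:
        X = X.T
    if event.sum() < 2:
        raise ValueError("Schoenfeld test needs at least 2 events")
    blocks = _split_strata(time, event, X, strata)
    info = np.zeros((len(fit.coef), len(fit.coef)))
    resid_parts, time_parts = [], []
    for t, d, Xs in blocks:
        if d.sum() == 0:
            continue
        _, _, binfo, bresid, btimes = _cox_quantities(
            fit.coef, t, d, Xs, fit.ties, want_resid=True
        )
        info += binfo
        resid_parts.append(bresid)
        time_parts.append(btimes)
    resid = np.concatenate(resid_parts)
    rtimes = np.concatenate(time_parts)
    d = len(rtimes)
    vinv = np.linalg.inv(info)
    scaled = resid @ vinv * d
    u = rtimes - rtimes.mean()
    test = u @ scaled
    denom = d * np.sum(u**2) * np.diag(vinv)
    chi2 = test**2 / denom
    return pd.DataFrame({
        "term": fit.terms,
        "chi2": chi2,
        "p": stats.chi2.sf(chi2, df=1),
    })
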