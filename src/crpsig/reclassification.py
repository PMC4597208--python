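"""Risk-model comparison: logistic models, cfNRI, IDI and bootstrap CIs.

The question answered here is whether adding the protein-signature score to
a base clinical risk model (by default donor age alone) moves individual
predicted risks in the right direction. Two model-free summaries quantify
this for a pair of risk vectors (p_base, p_new) and observed events:

* category-free net reclassification improvement (cfNRI): among events, the
  proportion whose risk went up minus the proportion whose risk went down;
  among non-events, down minus up; total = sum of the two components. The
  theoretical maximum is 200% (every event up, every non-event down).
* integrated discrimination improvement (IDI): mean risk change among
  events plus mean negative risk change among non-events; algebraically the
  difference in discrimination slopes between the two models.

Confidence intervals use a patient-level nonparametric bootstrap stratified
by event status (percentile method), or optionally the asymptotic normal
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .evaluation import DegenerateDataError

__all__ = [
    "LogisticFit",
    "RiskModelPair",
    "ReclassResult",
    "fit_logistic",
    "backward_select",
    "build_model_pair",
    "cfnri",
    "nri_curve",
    "idi",
    "bootstrap_ci",
    "analytic_ci",
]

#: Wald-statistic coefficient magnitude beyond which (on standardized-ish
#: clinical covariates / probabilities) we flag quasi-complete separation.
_SEPARATION_COEF = 15.0
_MAX_ITER = 200


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression summary (Wald inference)."""

    table: pd.DataFrame  # index: term; columns: coef, se, odds_ratio, or_ci_low, or_ci_high, p_value
    log_likelihood: float
    converged: bool
    separation: bool
    n: int
    removed: tuple[str, ...] = ()

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table.index if t != "const"]

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(design[self.terms], has_constant="add")
        beta = self.table["coef"].reindex(X.columns).to_numpy()
        eta = X.to_numpy(dtype=float) @ beta
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(design: pd.DataFrame, events: Sequence[bool]) -> LogisticFit:
    """Fit events ~ design by IRLS; flags non-convergence and separation."""
    y = np.asarray(events, dtype=float)
    if design.shape[0] != len(y):
        raise ValueError("design and outcome lengths differ")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more patients than covariates")
    constant = [c for c in design.columns if np.ptp(design[c].to_numpy(dtype=float)) == 0]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    X = sm.add_constant(design.astype(float), has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=_MAX_ITER)
    coefs = res.params
    ses = res.bse
    converged = bool(getattr(res, "converged", True)) and np.isfinite(ses).all()
    slope = coefs.drop("const", errors="ignore")
    separation = bool((np.abs(slope) > _SEPARATION_COEF).any() or not np.isfinite(ses).all())
    z = 1.959963984540054
    table = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "odds_ratio": np.exp(coefs),
            "or_ci_low": np.exp(coefs - z * ses),
            "or_ci_high": np.exp(coefs + z * ses),
            "p_value": res.pvalues,
        }
    )
    return LogisticFit(
        table=table,
        log_likelihood=float(res.llf),
        converged=converged,
        separation=separation,
        n=len(y),
    )


def backward_select(
    design: pd.DataFrame, events: Sequence[bool], retention_p: float = 0.05
) -> LogisticFit:
    """Backward elimination on Wald p-values at the given retention level.

    Repeatedly removes the covariate with the largest p >= retention_p and
    refits; the removal order is recorded on the returned fit. If nothing
    survives, the intercept-only fit is returned (flagged by an empty term
    list).
    """
    cols = list(design.columns)
    removed: list[str] = []
    while cols:
        fit = fit_logistic(design[cols], events)
        pvals = fit.table["p_value"].drop("const", errors="ignore")
        worst = pvals.idxmax()
        if pvals[worst] < retention_p:
            return LogisticFit(
                table=fit.table,
                log_likelihood=fit.log_likelihood,
                converged=fit.converged,
                separation=fit.separation,
                n=fit.n,
                removed=tuple(removed),
            )
        cols.remove(worst)
        removed.append(worst)
    # intercept-only fallback
    y = np.asarray(events, dtype=float)
    p0 = y.mean()
    const = np.log(p0 / (1 - p0))
    table = pd.DataFrame(
        {
            "coef": [const],
            "se": [np.sqrt(1 / (len(y) * p0 * (1 - p0)))],
            "odds_ratio": [np.exp(const)],
            "or_ci_low": [np.nan],
            "or_ci_high": [np.nan],
            "p_value": [np.nan],
        },
        index=["const"],
    )
    ll = float((y * np.log(p0) + (1 - y) * np.log(1 - p0)).sum())
    return LogisticFit(
        table=table, log_likelihood=ll, converged=True, separation=False, n=len(y),
        removed=tuple(removed),
    )


@dataclass(frozen=True)
class RiskModelPair:
    """Per-patient predicted risks under the base and extended models."""

    p_base: np.ndarray
    p_new: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        pb = np.asarray(self.p_base, dtype=float)
        pn = np.asarray(self.p_new, dtype=float)
        ev = np.asarray(self.event, dtype=bool)
        if not (pb.shape == pn.shape == ev.shape):
            raise ValueError("component lengths differ")
        if ((pb < 0) | (pb > 1) | (pn < 0) | (pn > 1)).any():
            raise ValueError("risks must lie in [0, 1]")
        object.__setattr__(self, "p_base", pb)
        object.__setattr__(self, "p_new", pn)
        object.__setattr__(self, "event", ev)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def n_nonevents(self) -> int:
        return int((~self.event).sum())


def build_model_pair(
    covariates: pd.DataFrame,
    signature_score: Sequence[float],
    events: Sequence[bool],
    signature_form: str = "probability",
) -> tuple[RiskModelPair, LogisticFit, LogisticFit]:
    """Base model from clinical covariates; extended model adds the signature.

    ``signature_form="probability"`` enters the out-of-fold probability as a
    continuous covariate; ``"class"`` dichotomizes it at 0.5 first.
    Returns the risk pair plus both fitted models.
    """
    score = np.asarray(signature_score, dtype=float)
    if signature_form == "class":
        score = (score >= 0.5).astype(float)
    elif signature_form != "probability":
        raise ValueError("signature_form must be 'probability' or 'class'")
    ev = np.asarray(events, dtype=bool)
    base_fit = fit_logistic(covariates, ev)
    extended = covariates.copy()
    if np.ptp(score) == 0:
        # a constant score carries no information: extended model == base
        new_fit = base_fit
        extended = covariates
    else:
        extended["signature"] = score
        new_fit = fit_logistic(extended, ev)
    pair = RiskModelPair(
        p_base=base_fit.predict(covariates),
        p_new=new_fit.predict(extended),
        event=ev,
    )
    return pair, base_fit, new_fit


@dataclass(frozen=True)
class ReclassResult:
    """cfNRI and/or IDI components; percentages for cfNRI, probabilities for IDI."""

    n_events: int
    n_nonevents: int
    events_up: int | None = None
    events_down: int | None = None
    nonevents_up: int | None = None
    nonevents_down: int | None = None
    cfnri_events: float | None = None
    cfnri_nonevents: float | None = None
    cfnri_total: float | None = None
    idi_events: float | None = None
    idi_nonevents: float | None = None
    idi_total: float | None = None
    ci95: dict = field(default_factory=dict)


def _require_groups(pair: RiskModelPair) -> None:
    if pair.n_events == 0 or pair.n_nonevents == 0:
        raise DegenerateDataError("both events and non-events required")


def cfnri(pair: RiskModelPair, threshold: float = 0.0) -> ReclassResult:
    """Category-free NRI at a risk-change threshold (0 = any movement).

    A patient moves "up" when p_new - p_base > threshold and "down" when
    p_base - p_new > threshold; exact ties move neither way. Components and
    the total are reported in percent; the total is bounded by 200%.
    """
    _require_groups(pair)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    d = pair.p_new - pair.p_base
    up, down = d > threshold, -d > threshold
    e = pair.event
    ev_up, ev_down = int((up & e).sum()), int((down & e).sum())
    ne_up, ne_down = int((up & ~e).sum()), int((down & ~e).sum())
    c_ev = 100.0 * (ev_up - ev_down) / pair.n_events
    c_ne = 100.0 * (ne_down - ne_up) / pair.n_nonevents
    return ReclassResult(
        n_events=pair.n_events,
        n_nonevents=pair.n_nonevents,
        events_up=ev_up,
        events_down=ev_down,
        nonevents_up=ne_up,
        nonevents_down=ne_down,
        cfnri_events=c_ev,
        cfnri_nonevents=c_ne,
        cfnri_total=c_ev + c_ne,
    )


def nri_curve(pair: RiskModelPair, thresholds: Sequence[float]) -> pd.DataFrame:
    """cfNRI components as a function of the risk-change threshold."""
    rows = []
    for t in thresholds:
        r = cfnri(pair, threshold=float(t))
        rows.append(
            {
                "threshold": float(t),
                "cfnri_events": r.cfnri_events,
                "cfnri_nonevents": r.cfnri_nonevents,
                "cfnri_total": r.cfnri_total,
            }
        )
    return pd.DataFrame(rows)


def idi(pair: RiskModelPair) -> ReclassResult:
    """Integrated discrimination improvement (difference in mean risks)."""
    _require_groups(pair)
    e = pair.event
    i_ev = float(pair.p_new[e].mean() - pair.p_base[e].mean())
    i_ne = float(pair.p_base[~e].mean() - pair.p_new[~e].mean())
    return ReclassResult(
        n_events=pair.n_events,
        n_nonevents=pair.n_nonevents,
        idi_events=i_ev,
        idi_nonevents=i_ne,
        idi_total=i_ev + i_ne,
    )


_COMPONENTS = {
    "cfnri": ("cfnri_events", "cfnri_nonevents", "cfnri_total"),
    "idi": ("idi_events", "idi_nonevents", "idi_total"),
}


def _statistic_values(pair: RiskModelPair, statistic: str, threshold: float) -> dict[str, float]:
    r = cfnri(pair, threshold) if statistic == "cfnri" else idi(pair)
    return {k: getattr(r, k) for k in _COMPONENTS[statistic]}


def bootstrap_ci(
    pair: RiskModelPair,
    statistic: str = "cfnri",
    reps: int = 2000,
    seed: int = 0,
    threshold: float = 0.0,
) -> dict[str, tuple[float, float]]:
    """Stratified patient-level bootstrap percentile 95% CIs per component.

    Events and non-events are resampled separately (with replacement),
    which guarantees both groups stay non-empty in every resample.
    """
    if statistic not in _COMPONENTS:
        raise ValueError("statistic must be 'cfnri' or 'idi'")
    if reps < 100:
        raise ValueError("reps must be at least 100")
    _require_groups(pair)
    rng = np.random.default_rng(seed)
    e_idx = np.flatnonzero(pair.event)
    n_idx = np.flatnonzero(~pair.event)
    samples = {k: np.empty(reps) for k in _COMPONENTS[statistic]}
    for b in range(reps):
        take = np.concatenate(
            [rng.choice(e_idx, size=len(e_idx)), rng.choice(n_idx, size=len(n_idx))]
        )
        res = _statistic_values(
            RiskModelPair(pair.p_base[take], pair.p_new[take], pair.event[take]),
            statistic,
            threshold,
        )
        for k, v in res.items():
            samples[k][b] = v
    return {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in samples.items()
    }


def analytic_ci(
    pair: RiskModelPair, statistic: str = "idi", threshold: float = 0.0
) -> dict[str, tuple[float, float]]:
    """Asymptotic normal 95% CIs (alternative to the bootstrap).

    cfNRI components are differences of multinomial proportions; IDI
    components are means of per-patient risk differences.
    """
    _require_groups(pair)
    z = 1.959963984540054
    e = pair.event
    out: dict[str, tuple[float, float]] = {}
    if statistic == "cfnri":
        d = pair.p_new - pair.p_base
        comps = {}
        for key, mask in (("cfnri_events", e), ("cfnri_nonevents", ~e)):
            n = int(mask.sum())
            pu = float((d[mask] > threshold).mean())
            pd_ = float((-d[mask] > threshold).mean())
            est = 100.0 * ((pu - pd_) if key == "cfnri_events" else (pd_ - pu))
            se = 100.0 * np.sqrt((pu + pd_ - (pu - pd_) ** 2) / n)
            comps[key] = (est, se)
        tot = comps["cfnri_events"][0] + comps["cfnri_nonevents"][0]
        se_t = np.hypot(comps["cfnri_events"][1], comps["cfnri_nonevents"][1])
        for k, (est, se) in comps.items():
            out[k] = (est - z * se, est + z * se)
        out["cfnri_total"] = (tot - z * se_t, tot + z * se_t)
    elif statistic == "idi":
        d = pair.p_new - pair.p_base
        m_ev, se_ev = float(d[e].mean()), float(d[e].std(ddof=1) / np.sqrt(e.sum()))
        m_ne, se_ne = float(-d[~e].mean()), float(d[~e].std(ddof=1) / np.sqrt((~e).sum()))
        out["idi_events"] = (m_ev - z * se_ev, m_ev + z * se_ev)
        out["idi_nonevents"] = (m_ne - z * se_ne, m_ne + z * se_ne)
        tot, se_t = m_ev + m_ne, float(np.hypot(se_ev, se_ne))
        out["idi_total"] = (tot - z * se_t, tot + z * se_t)
    else:
        raise ValueError("statistic must be 'cfnri' or 'idi'")
    return out
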