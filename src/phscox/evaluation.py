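"""Scoring and evaluation of polygenic hazard scores on held-out cohorts.

A fitted model defines the polygenic hazard score (PHS): the
variant-only linear predictor sum_j beta_j * (x_j - mean_j) / sd_j with
the training-split standardization. Predictive power on a cohort that
played no part in training is summarized the way progression PHS
studies report it:

* Harrell's concordance index over comparable pairs;
* the hazard ratio per standard deviation of the score ("scale HR"),
  from a single-covariate Cox fit with a Wald p-value;
* hazard ratios of percentile extremes (top 1/5/10%, bottom 10%) each
  against the 40-60% reference group;
* Kaplan-Meier curves per percentile group with cumulative incidence
  read off at fixed horizons after the baseline diagnosis.

Group HR models are unadjusted by default (score or group indicator
only); ``adjusted=True`` adds the standard covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coxph import fit_cox_newton, make_cox_data
from .genotypes import GenotypeStore
from .phenotypes import ProgressionDataset

__all__ = [
    "PHSScores",
    "HRResult",
    "KMCurve",
    "EvaluationReport",
    "compute_phs",
    "c_index",
    "hr_per_sd",
    "percentile_hr",
    "km_curves",
    "evaluate",
]

PERCENTILE_GROUPS = ("top1", "top5", "top10", "reference", "bottom10")
DEFAULT_HORIZONS = (1.0, 10.0, 15.0, 22.0)


@dataclass
class PHSScores:
    """Per-person score with its within-cohort percentile rank.

    Ranks are a monotone transform of the score in (0, 1]; tied scores
    are broken by stable person-id order so grouping is deterministic.
    """

    person_ids: np.ndarray
    phs: np.ndarray
    percentile_rank: np.ndarray = field(default=None)

    def __post_init__(self):
        self.person_ids = np.asarray(self.person_ids)
        self.phs = np.asarray(self.phs, dtype=np.float64)
        if self.percentile_rank is None:
            n = len(self.phs)
            order = np.lexsort((self.person_ids, self.phs))
            rank = np.empty(n)
            rank[order] = (np.arange(n) + 1) / n
            self.percentile_rank = rank

    def __len__(self) -> int:
        return len(self.phs)

    def groups(self) -> dict:
        """Percentile group masks: top1 c top5 c top10; reference is
        the (40%, 60%] band; bottom10 is the lowest decile."""
        r = self.percentile_rank
        return {
            "top1": r > 0.99,
            "top5": r > 0.95,
            "top10": r > 0.90,
            "reference": (r > 0.40) & (r <= 0.60),
            "bottom10": r <= 0.10,
        }


def compute_phs(
    store: GenotypeStore,
    model,
    row_indices: np.ndarray | None = None,
) -> PHSScores:
    """Score individuals with a fitted model's variant weights.

    Missing model variants are skipped with a warning; more than 10%
    absent is a hard error because the score is no longer comparable to
    the training scale. Missing genotype calls are imputed with the
    model's training means. Deterministic, and invariant to the variant
    order in the model file.
    """
    rows = (
        np.arange(store.n_individuals) if row_indices is None else np.asarray(row_indices)
    )
    ids = store.variants["id"].to_numpy()
    pos_by_id = pd.Series(np.arange(len(ids)), index=ids)
    present = np.isin(model.variant_ids, ids)
    n_model = len(model.variant_ids)
    if n_model and (~present).sum() > 0.10 * n_model:
        raise ValueError(
            f"{(~present).sum()}/{n_model} model variants absent from the store; "
            "score not comparable"
        )
    if (~present).any():
        warnings.warn(f"skipping {(~present).sum()} model variant(s) absent from the store")
    phs = np.zeros(rows.size)
    if present.any():
        cols = pos_by_id.loc[model.variant_ids[present]].to_numpy()
        block = store.dosages(cols, rows)
        mu = model.mean[present]
        block = np.where(np.isnan(block), mu, block)
        phs = ((block - mu) / model.sd[present]) @ model.betas[present]
    return PHSScores(person_ids=store.sample_ids[rows], phs=phs)


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------
def c_index(scores, y, status) -> float:
    """Harrell's concordance over comparable pairs.

    A pair (i, j) is comparable when i has an event strictly before
    y_j; it is concordant when the earlier-event individual carries the
    higher score, and tied scores count 1/2. Pairs that are both
    censored, censored before the other's event, or tied in time are
    incomparable.
    """
    s = np.asarray(getattr(scores, "phs", scores), dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    status = np.asarray(status)
    conc = ties = total = 0
    for i in np.flatnonzero(status == 1):
        later = y > y[i]
        m = int(later.sum())
        if m:
            conc += int((s[i] > s[later]).sum())
            ties += int((s[i] == s[later]).sum())
            total += m
    if total == 0:
        raise ValueError("no comparable pairs; concordance undefined")
    return (conc + 0.5 * ties) / total


@dataclass
class HRResult:
    """Hazard ratio with Wald inference from a small Cox fit."""

    hr: float
    p: float
    beta: float
    se: float
    ci_low: float
    ci_high: float
    n: int

    @classmethod
    def from_fit(cls, beta: float, se: float, n: int) -> "HRResult":
        z = beta / se
        return cls(
            hr=float(np.exp(beta)),
            p=float(2.0 * sps.norm.sf(abs(z))),
            beta=float(beta),
            se=float(se),
            ci_low=float(np.exp(beta - 1.959963984540054 * se)),
            ci_high=float(np.exp(beta + 1.959963984540054 * se)),
            n=n,
        )


def _single_hr(x: np.ndarray, y, status, extra: np.ndarray | None = None) -> HRResult:
    X = x[:, None] if extra is None else np.column_stack([x, extra])
    data = make_cox_data(y, status, X_unpen=X)
    fit = fit_cox_newton(data)
    if not fit.converged:
        raise RuntimeError("Cox fit for the hazard ratio did not converge; inspect the score")
    return HRResult.from_fit(fit.beta[0], fit.se[0], len(y))


def hr_per_sd(scores, y, status, adjust: np.ndarray | None = None) -> HRResult:
    """Hazard ratio per standard deviation of the score (the scale HR).

    Fits a Cox model with the single covariate phs / SD(phs) on the
    evaluation cohort (Breslow ties, Newton-Raphson); the p-value is the
    Wald test. Invariant to affine rescaling of the score.
    """
    s = np.asarray(getattr(scores, "phs", scores), dtype=np.float64)
    sd = s.std()
    if sd == 0:
        raise ValueError("score variance is zero; HR per SD undefined")
    return _single_hr((s - s.mean()) / sd, y, status, extra=adjust)


def percentile_hr(
    scores: PHSScores, y, status, adjust: np.ndarray | None = None
) -> dict:
    """HR of each percentile extreme against the 40-60% reference group.

    Entries are None when the comparison is degenerate (empty group or
    no events among the pooled pair of groups), mirroring blank report
    cells.
    """
    y = np.asarray(y, dtype=np.float64)
    status = np.asarray(status)
    g = scores.groups()
    ref = g["reference"]
    out = {}
    for name in ("top1", "top5", "top10", "bottom10"):
        grp = g[name]
        sel = grp | ref
        if grp.sum() == 0 or ref.sum() == 0 or status[sel].sum() == 0:
            out[name] = None
            continue
        ind = grp[sel].astype(np.float64)
        try:
            out[name] = _single_hr(
                ind, y[sel], status[sel], extra=None if adjust is None else adjust[sel]
            )
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            out[name] = None
    return out


@dataclass
class KMCurve:
    """Product-limit survival curve for one percentile group."""

    group: str
    times: np.ndarray  # event times (step locations)
    survival: np.ndarray  # S(t) just after each step, starts below 1
    n_at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray  # tick marks
    incidence: dict  # horizon -> 1 - S(horizon)

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curves(
    scores: PHSScores, y, status, horizons=DEFAULT_HORIZONS
) -> dict:
    """Kaplan-Meier curves per percentile group (lifelines backend)."""
    from lifelines import KaplanMeierFitter

    y = np.asarray(y, dtype=np.float64)
    status = np.asarray(status)
    curves = {}
    for name, mask in scores.groups().items():
        if mask.sum() == 0:
            curves[name] = None
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(y[mask], status[mask])
        tbl = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
        ev = tbl[tbl["observed"] > 0]
        times = ev.index.to_numpy(dtype=np.float64)
        surv = kmf.survival_function_at_times(times).to_numpy()
        incid = {
            float(h): float(1.0 - kmf.survival_function_at_times(h).iloc[0]) for h in horizons
        }
        curves[name] = KMCurve(
            group=name,
            times=times,
            survival=surv,
            n_at_risk=ev["at_risk"].to_numpy(dtype=np.int64),
            n_events=ev["observed"].to_numpy(dtype=np.int64),
            censor_times=np.sort(y[mask][np.asarray(status)[mask] == 0]),
            incidence=incid,
        )
    return curves


# ----------------------------------------------------------------------
# the report
# ----------------------------------------------------------------------
@dataclass
class EvaluationReport:
    """One PHS evaluated on one cohort: the standard reporting battery."""

    cohort_name: str
    n: int
    n_cases: int
    n_active_variants: int
    scale: HRResult
    c_index: float
    percentile_hrs: dict
    km: dict
    scores: PHSScores

    def summary(self) -> pd.DataFrame:
        rows = {
            "cohort": self.cohort_name,
            "n": self.n,
            "n_cases": self.n_cases,
            "active_variables": self.n_active_variants,
            "scale_hr": self.scale.hr,
            "scale_p": self.scale.p,
            "scale_c_index": self.c_index,
        }
        for name in ("top1", "top5", "top10", "bottom10"):
            r = self.percentile_hrs.get(name)
            rows[f"hr_{name}"] = r.hr if r else np.nan
            rows[f"p_{name}"] = r.p if r else np.nan
        return pd.DataFrame([rows])

    def km_long(self) -> pd.DataFrame:
        frames = []
        for name, c in self.km.items():
            if c is None:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "group": name,
                        "time": c.times,
                        "survival": c.survival,
                        "n_at_risk": c.n_at_risk,
                        "n_events": c.n_events,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def evaluate(
    model,
    cohort: ProgressionDataset,
    store: GenotypeStore,
    horizons=DEFAULT_HORIZONS,
    adjusted: bool = False,
    cohort_name: str = "test",
) -> EvaluationReport:
    """Assemble the full evaluation battery on a held-out cohort.

    The cohort must be disjoint from the model's training individuals
    (checked by person-id overlap). With ``adjusted=True`` the scale and
    group HR models include the cohort covariates.
    """
    train_ids = set(np.asarray(model.train_person_ids).tolist())
    overlap = train_ids & set(cohort.person_ids.tolist())
    if overlap:
        raise ValueError(
            f"evaluation cohort overlaps training set ({len(overlap)} person(s))"
        )
    sample_pos = pd.Series(np.arange(store.n_individuals), index=store.sample_ids)
    rows = sample_pos.loc[cohort.person_ids].to_numpy()
    scores = compute_phs(store, model, rows)
    adjust = cohort.covariate_matrix() if adjusted else None
    if scores.phs.std() == 0:
        # an empty (or constant) PHS is a legitimate outcome of model
        # selection on null data: report it rather than fail
        warnings.warn("PHS is constant on this cohort; scale and group HRs undefined")
        nan_hr = HRResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, len(cohort))
        return EvaluationReport(
            cohort_name=cohort_name,
            n=len(cohort),
            n_cases=cohort.n_cases,
            n_active_variants=model.n_active,
            scale=nan_hr,
            c_index=c_index(scores, cohort.y, cohort.status),
            percentile_hrs={k: None for k in ("top1", "top5", "top10", "bottom10")},
            km=km_curves(scores, cohort.y, cohort.status, horizons=horizons),
            scores=scores,
        )
    return EvaluationReport(
        cohort_name=cohort_name,
        n=len(cohort),
        n_cases=cohort.n_cases,
        n_active_variants=model.n_active,
        scale=hr_per_sd(scores, cohort.y, cohort.status, adjust=adjust),
        c_index=c_index(scores, cohort.y, cohort.status),
        percentile_hrs=percentile_hr(scores, cohort.y, cohort.status, adjust=adjust),
        km=km_curves(scores, cohort.y, cohort.status, horizons=horizons),
        scores=scores,
    )
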