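"""Synthetic genotypes, Cox survival outcomes and mock EHR event tables.

The generator reproduces the statistical structure the pipeline assumes
so that every stage is testable without any download:

* biallelic genotypes drawn binomial(2, MAF) per variant with
  completely-at-random missing calls (no linkage disequilibrium —
  independent variants keep recovery tests clean and the pipeline is
  LD-agnostic);
* a sparse causal architecture: a handful of causal variants with
  log-hazard effects on the per-standard-deviation scale;
* event times from a Cox model with a constant (exponential) baseline
  hazard, independent exponential censoring calibrated by bisection to a
  target censored fraction, and an optional rounding grid to inject tied
  event times (real ages-in-months data is heavily tied);
* mock per-person EHR event tables with birth month/year fields,
  baseline and outcome codes, and controlled quotas of registry
  sentinel dates so date-cleaning behaviour can be asserted exactly.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeStore
from .phenotypes import ProgressionDataset

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "EHRTables",
    "gen_genotypes",
    "gen_causal_effects",
    "gen_covariates",
    "gen_survival",
    "gen_ehr_events",
    "write_simulation",
]

PC_COLUMNS = [f"PC{i}" for i in range(1, 11)]
COVARIATE_COLUMNS = ["age_at_baseline", "sex", "array"] + PC_COLUMNS


@dataclass
class SimConfig:
    """Simulation knobs for one synthetic cohort.

    Defaults describe the standing study conditions used throughout the
    test battery: 4,000 individuals, 2,000 common variants, 15 causal
    variants with per-SD log-hazard effects of magnitude 0.1-0.3, an
    exponential baseline hazard of 0.05 events/year from baseline
    diagnosis, and 30% of follow-up right-censored.
    """

    n_individuals: int = 4000
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 15
    effect_scale: float = 0.3  # |beta| ~ U(effect_scale/3, effect_scale) per SD
    baseline_hazard_rate: float = 0.05  # events per year
    censoring_rate: float = 0.30
    missing_genotype_rate: float = 0.01
    seed: int = 0
    time_granularity: float | None = None  # e.g. 1/12 rounds times to months
    age_effect: float = 0.03  # log-hazard per year of baseline age (centered)
    sex_effect: float = 0.25  # log-hazard, second sex vs first

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.n_causal <= self.n_variants:
            raise ValueError("n_causal must be in [0, n_variants]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if not 0.0 <= self.missing_genotype_rate < 1.0:
            raise ValueError("missing_genotype_rate must be in [0, 1)")
        if self.n_individuals < 2 or self.n_variants < 1:
            raise ValueError("need at least 2 individuals and 1 variant")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline_hazard_rate must be > 0")
        if self.time_granularity is not None and self.time_granularity <= 0:
            raise ValueError("time_granularity must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth of the causal architecture, for recovery tests."""

    causal_indices: np.ndarray
    causal_betas: np.ndarray  # log-hazard per SD of genotype
    true_linear_predictor: np.ndarray | None = None

    def __post_init__(self):
        self.causal_indices = np.asarray(self.causal_indices, dtype=np.int64)
        self.causal_betas = np.asarray(self.causal_betas, dtype=np.float64)
        if len(self.causal_indices) != len(self.causal_betas):
            raise ValueError("causal_indices and causal_betas lengths differ")

    @property
    def sd_linear_predictor(self) -> float:
        """Population SD of the genetic linear predictor (independent,
        standardized variants): sqrt(sum beta_j^2)."""
        return float(np.sqrt(np.sum(self.causal_betas**2)))

    def to_tsv(self, path, variant_ids=None) -> None:
        ids = (
            np.asarray(variant_ids)[self.causal_indices]
            if variant_ids is not None
            else self.causal_indices
        )
        pd.DataFrame(
            {"variant_index": self.causal_indices, "variant_id": ids, "beta": self.causal_betas}
        ).to_csv(path, sep="\t", index=False)


def gen_genotypes(config: SimConfig) -> GenotypeStore:
    """Simulate the biallelic dosage matrix with per-variant metadata.

    Variant j has its allele frequency drawn uniformly on ``maf_range``
    and dosages binomial(2, maf_j); a fraction
    ``missing_genotype_rate`` of entries is set missing uniformly at
    random. MAF and missing-rate metadata are populated on the full
    cohort.
    """
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(*config.maf_range, size=config.n_variants)
    g = rng.binomial(2, mafs, size=(config.n_individuals, config.n_variants)).astype(np.int8)
    if config.missing_genotype_rate > 0:
        mask = rng.random(g.shape) < config.missing_genotype_rate
        g[mask] = -1
    ids = [f"rs{j:06d}" for j in range(config.n_variants)]
    return GenotypeStore.from_arrays(g, variant_ids=ids)


def gen_causal_effects(config: SimConfig) -> SyntheticTruth:
    """Sparse causal architecture: which variants act, and how strongly."""
    rng = np.random.default_rng(config.seed + 1)
    idx = np.sort(rng.choice(config.n_variants, size=config.n_causal, replace=False))
    mag = rng.uniform(config.effect_scale / 3.0, config.effect_scale, size=config.n_causal)
    sign = rng.choice([-1.0, 1.0], size=config.n_causal)
    return SyntheticTruth(causal_indices=idx, causal_betas=mag * sign)


def gen_covariates(config: SimConfig) -> pd.DataFrame:
    """Adjustment covariates: baseline age, sex, array, 10 genetic PCs."""
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_individuals
    return pd.DataFrame(
        {
            "age_at_baseline": rng.uniform(40.0, 70.0, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "array": rng.integers(0, 2, n).astype(float),
            **{c: rng.standard_normal(n) for c in PC_COLUMNS},
        }
    )


def _standardized_causal(store: GenotypeStore, truth: SyntheticTruth) -> np.ndarray:
    block = store.dosages(truth.causal_indices)
    mu = np.nanmean(block, axis=0)
    block = np.where(np.isnan(block), mu, block)
    sd = block.std(axis=0)
    sd[sd == 0] = 1.0
    return (block - mu) / sd


def gen_survival(
    genotypes: GenotypeStore,
    truth: SyntheticTruth,
    config: SimConfig,
    covariates: pd.DataFrame | None = None,
) -> ProgressionDataset:
    """Cox-model event times with right censoring.

    Event times are exponential with rate
    ``baseline_hazard_rate * exp(eta)``, eta the genetic linear
    predictor over standardized causal genotypes plus the covariate
    contribution. Censoring times are exponential with a rate found by
    bisection so the expected censored fraction matches
    ``censoring_rate`` (to well within +-0.02); status is 1 iff the
    event precedes censoring. Times are strictly positive; with
    ``time_granularity`` set they are rounded up to that grid to inject
    ties.
    """
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_individuals
    if covariates is None:
        covariates = gen_covariates(config)
    eta = np.zeros(n)
    if truth.causal_indices.size:
        eta += _standardized_causal(genotypes, truth) @ truth.causal_betas
    truth.true_linear_predictor = eta.copy()  # genetic component only
    eta_full = (
        eta
        + config.age_effect * (covariates["age_at_baseline"].to_numpy() - 55.0)
        + config.sex_effect * covariates["sex"].to_numpy()
    )
    rate = config.baseline_hazard_rate * np.exp(eta_full)
    T = rng.exponential(1.0 / rate)
    if config.censoring_rate == 0.0:
        y, status = T, np.ones(n, dtype=np.int64)
    else:
        c = _calibrate_censoring_rate(T, config.censoring_rate)
        C = rng.exponential(1.0 / c, size=n)
        y = np.minimum(T, C)
        status = (T <= C).astype(np.int64)
    if config.time_granularity is not None:
        y = np.ceil(y / config.time_granularity) * config.time_granularity
    y = np.maximum(y, 1e-9)
    return ProgressionDataset(
        person_ids=np.array([f"iid_{i}" for i in range(n)]),
        y=y,
        status=status,
        covariates=covariates,
        name="simulated",
    )


def _calibrate_censoring_rate(T: np.ndarray, target: float) -> float:
    """Censoring hazard c with mean_i P(C < T_i) = target, C ~ Exp(c)."""

    def frac(c):
        return float(np.mean(1.0 - np.exp(-c * T)))

    lo, hi = 1e-12, 1.0 / np.mean(T)
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ----------------------------------------------------------------------
# mock EHR event tables
# ----------------------------------------------------------------------
@dataclass
class EHRTables:
    """Raw mock EHR tables plus the injected anomaly quotas.

    ``events`` has columns person_id, code, date, source; ``births``
    maps each person to month/year of birth; ``deaths`` is a person_id
    -> death date series. ``quotas`` records exactly how many records of
    each anomaly category were injected, so cleaning and derivation
    reports can be asserted record-for-record.
    """

    events: pd.DataFrame
    births: pd.DataFrame
    deaths: pd.Series
    quotas: dict = field(default_factory=dict)

    @property
    def dob(self) -> pd.Series:
        from .phenotypes import compute_dob

        return pd.Series(
            [
                compute_dob(m, y)
                for m, y in zip(self.births["birth_month"], self.births["birth_year"])
            ],
            index=self.births["person_id"].to_numpy(),
        )


BASELINE_CODE = "E78"  # hyperlipidemia-style 3-character diagnosis code
OUTCOME_CODE = "K451"  # CABG-style OPCS-4 procedure code
FILLER_CODE = "Z99"  # matches neither code set; carries injected anomalies


def gen_ehr_events(
    n_individuals: int,
    seed: int,
    outcome_fraction: float = 0.3,
    death_fraction: float = 0.1,
    n_sentinel_1902: int = 5,
    n_sentinel_1903: int = 4,
    n_sentinel_2037: int = 3,
    n_sentinel_1900: int = 3,
    n_before_birth: int = 4,
    n_outcome_before_baseline: int = 3,
) -> EHRTables:
    """Mock EHR event table with controlled anomaly quotas.

    Every person gets a baseline diagnosis; a fraction gets a later
    outcome procedure, a disjoint quota gets an outcome *before* the
    baseline (to exercise the ordering exclusion), and a fraction dies
    before any outcome (censoring by death). Sentinel-date and
    before-birth anomalies are injected on filler-code records so their
    cleaning counts are exact.
    """
    rng = np.random.default_rng(seed)
    n = int(n_individuals)
    pid = np.array([f"iid_{i}" for i in range(n)])
    births = pd.DataFrame(
        {
            "person_id": pid,
            "birth_month": rng.integers(1, 13, n),
            "birth_year": rng.integers(1940, 1966, n),
        }
    )
    dob = pd.to_datetime(
        pd.DataFrame(
            {"year": births["birth_year"], "month": births["birth_month"], "day": 1}
        )
    ).to_numpy()

    base_age_days = rng.uniform(30.0, 55.0, n) * 365.25
    base_date = dob + base_age_days.astype("timedelta64[D]")

    rows = [
        pd.DataFrame(
            {"person_id": pid, "code": BASELINE_CODE, "date": base_date, "source": "inpatient"}
        )
    ]

    # disjoint person groups for outcome-ordering behaviour
    order = rng.permutation(n)
    n_pre = min(n_outcome_before_baseline, n)
    pre_idx = order[:n_pre]
    rest = order[n_pre:]
    n_out = int(round(outcome_fraction * len(rest)))
    out_idx = rest[:n_out]
    n_death = int(round(death_fraction * len(rest[n_out:])))
    death_idx = rest[n_out : n_out + n_death]

    out_delay = rng.uniform(0.5, 12.0, n_out) * 365.25
    out_date = base_date[out_idx] + out_delay.astype("timedelta64[D]")
    rows.append(
        pd.DataFrame(
            {"person_id": pid[out_idx], "code": OUTCOME_CODE, "date": out_date, "source": "procedure"}
        )
    )
    pre_date = base_date[pre_idx] - (rng.uniform(0.5, 5.0, n_pre) * 365.25).astype("timedelta64[D]")
    rows.append(
        pd.DataFrame(
            {"person_id": pid[pre_idx], "code": OUTCOME_CODE, "date": pre_date, "source": "procedure"}
        )
    )
    death_date = base_date[death_idx] + (rng.uniform(0.5, 10.0, n_death) * 365.25).astype(
        "timedelta64[D]"
    )
    deaths = pd.Series(death_date, index=pid[death_idx])
    rows.append(
        pd.DataFrame(
            {"person_id": pid[death_idx], "code": "R99", "date": death_date, "source": "death"}
        )
    )

    # sentinel and before-birth anomalies on filler-code records
    def _filler(k, dates):
        who = rng.integers(0, n, k)
        return pd.DataFrame(
            {"person_id": pid[who], "code": FILLER_CODE, "date": dates, "source": "primary_care"}
        ), who

    f, _ = _filler(n_sentinel_1902, pd.Timestamp("1902-02-02"))
    rows.append(f)
    f, _ = _filler(n_sentinel_1903, pd.Timestamp("1903-03-03"))
    rows.append(f)
    f, _ = _filler(n_sentinel_2037, pd.Timestamp("2037-07-07"))
    rows.append(f)
    f, _ = _filler(n_sentinel_1900, pd.Timestamp("1900-01-01"))
    rows.append(f)
    who = rng.integers(0, n, n_before_birth)
    bb_dates = dob[who] - rng.integers(1, 32, n_before_birth).astype("timedelta64[D]")
    rows.append(
        pd.DataFrame(
            {"person_id": pid[who], "code": FILLER_CODE, "date": bb_dates, "source": "primary_care"}
        )
    )

    events = pd.concat(rows, ignore_index=True)
    events["date"] = pd.to_datetime(events["date"])
    quotas = {
        "to_dob_1902": n_sentinel_1902,
        "to_dob_plus_6m_1903": n_sentinel_1903,
        "removed_2037": n_sentinel_2037,
        "removed_1900": n_sentinel_1900,
        "month_before_birth_to_dob": n_before_birth,
        "outcome_before_baseline": n_pre,
        "deaths_before_outcome": n_death,
        "with_outcome": n_out,
    }
    return EHRTables(events=events, births=births, deaths=deaths, quotas=quotas)


def write_simulation(
    out_dir, config: SimConfig
) -> tuple[GenotypeStore, SyntheticTruth, ProgressionDataset]:
    """Generate one full cohort and write every artifact to ``out_dir``.

    Writes genotypes as PLINK BED/BIM/FAM, the phenotype/covariate table
    and causal truth as TSV, and the mock EHR tables (events, births,
    deaths).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    store = gen_genotypes(config)
    truth = gen_causal_effects(config)
    pheno = gen_survival(store, truth, config)
    store.write_bed(out / "genotypes")
    pheno.to_tsv(out / "phenotype.tsv")
    truth.to_tsv(out / "truth.tsv", variant_ids=store.variants["id"].to_numpy())
    ehr = gen_ehr_events(config.n_individuals, config.seed + 4)
    ehr.events.to_csv(out / "ehr_events.tsv", sep="\t", index=False)
    ehr.births.to_csv(out / "ehr_births.tsv", sep="\t", index=False)
    ehr.deaths.rename("death_date").rename_axis("person_id").to_csv(
        out / "ehr_deaths.tsv", sep="\t"
    )
    return store, truth, pheno
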