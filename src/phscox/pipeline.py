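"""End-to-end pipeline: simulate -> phenotype -> qc -> fit -> evaluate.

One structured YAML config documents a run completely; every stage
reads its inputs from files written by the previous stage, so a run can
be resumed after deleting any intermediate. The manifest lists every
artifact with a checksum — reruns with the same seed produce identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import basil as _basil
from .evaluation import evaluate
from .genotypes import GenotypeStore, impute_and_standardize, qc_filter
from .phenotypes import (
    ProgressionDataset,
    ProgressionDefinition,
    check_case_thresholds,
    clean_event_dates,
    compute_dob,
    derive_progression,
)
from .simulate import SimConfig, write_simulation

log = logging.getLogger("phscox")

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "demo_config"]

STAGES = ("simulate", "phenotype", "qc", "fit", "evaluate")

DEFAULT_CONFIG: dict = {
    "simulate": {},  # SimConfig fields
    "phenotype": {
        "baseline_codes": ["E78"],
        "outcome_codes": ["K451"],
        "censor_date": "2020-03-01",
        "min_baseline_cases": 100,
        "min_outcome_cases": 10,
    },
    "qc": {"max_missing": 0.10, "min_maf": 0.001},
    "fit": {},  # BasilConfig fields
    "evaluate": {"horizons": [1.0, 10.0, 15.0, 22.0], "adjusted": False},
}

_OUTPUTS = {
    "simulate": [
        "genotypes.bed",
        "genotypes.bim",
        "genotypes.fam",
        "phenotype.tsv",
        "truth.tsv",
        "ehr_events.tsv",
        "ehr_births.tsv",
        "ehr_deaths.tsv",
    ],
    "phenotype": ["ehr_progression.tsv", "cleaning_report.tsv", "derivation_report.tsv"],
    "qc": ["qc_report.tsv"],
    "fit": ["path_summary.tsv", "path_coefficients.tsv", "model.tsv", "splits.tsv"],
    "evaluate": ["evaluation_summary.tsv", "km_curves.tsv"],
}


def demo_config() -> dict:
    """Desk-scale demo: 2,000 individuals, 500 variants, minutes on one CPU."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg["simulate"] = {"n_individuals": 2000, "n_variants": 500, "n_causal": 10}
    cfg["fit"] = {"n_lambda": 50, "batch_screen_size": 100}
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _merge(base: dict, override: dict | None) -> dict:
    out = json.loads(json.dumps(base))
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def run_pipeline(
    config: dict | None,
    out_dir,
    seed: int = 0,
    resume: bool = False,
) -> dict:
    """Run all stages, returning the artifact manifest.

    ``config`` overrides :data:`DEFAULT_CONFIG` block-wise. Each stage
    writes its artifacts under ``out_dir`` and later stages read them
    back from disk; with ``resume`` a stage whose outputs all exist (and
    whose upstream stages were not rerun) is skipped.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": {}}
    upstream_reran = False

    for stage in STAGES:
        paths = [out / f for f in _OUTPUTS[stage]]
        if resume and not upstream_reran and all(p.exists() for p in paths):
            log.info("stage %s: outputs present, skipped (resume)", stage)
            manifest["stages"][stage] = {p.name: _sha256(p) for p in paths}
            continue
        log.info("stage %s: running", stage)
        _RUNNERS[stage](cfg, out, seed)
        upstream_reran = True
        manifest["stages"][stage] = {p.name: _sha256(p) for p in paths}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ----------------------------------------------------------------------
# stage runners (file in, file out)
# ----------------------------------------------------------------------
def _stage_simulate(cfg: dict, out: Path, seed: int) -> None:
    sim_kwargs = dict(cfg["simulate"])
    sim_kwargs.setdefault("seed", seed)
    sc = SimConfig(**sim_kwargs)
    store, truth, pheno = write_simulation(out, sc)
    log.info(
        "simulated n=%d p=%d causal=%d events=%d",
        sc.n_individuals,
        sc.n_variants,
        sc.n_causal,
        pheno.n_cases,
    )


def _stage_phenotype(cfg: dict, out: Path, seed: int) -> None:
    events = pd.read_csv(out / "ehr_events.tsv", sep="\t", parse_dates=["date"])
    births = pd.read_csv(out / "ehr_births.tsv", sep="\t")
    deaths = pd.read_csv(out / "ehr_deaths.tsv", sep="\t", parse_dates=["death_date"])
    dob = pd.Series(
        [compute_dob(m, y) for m, y in zip(births["birth_month"], births["birth_year"])],
        index=births["person_id"].to_numpy(),
    )
    cleaned, report = clean_event_dates(events, dob)
    report.to_tsv(out / "cleaning_report.tsv")
    pcfg = cfg["phenotype"]
    definition = ProgressionDefinition(
        baseline_codes=frozenset(pcfg["baseline_codes"]),
        outcome_codes=frozenset(pcfg["outcome_codes"]),
        censor_date=pcfg["censor_date"],
        min_baseline_cases=pcfg["min_baseline_cases"],
        min_outcome_cases=pcfg["min_outcome_cases"],
    )
    death_series = pd.Series(
        deaths["death_date"].to_numpy(), index=deaths["person_id"].to_numpy()
    )
    ds, dreport = derive_progression(cleaned, definition, death_series, dob)
    ds.to_tsv(out / "ehr_progression.tsv")
    check = check_case_thresholds(ds, definition)
    pd.DataFrame(
        {
            "category": [
                "included",
                "excluded_by_ordering",
                "no_baseline",
                "n_cases",
                "thresholds_passed",
            ],
            "count": [
                dreport.included,
                dreport.excluded_by_ordering,
                dreport.no_baseline,
                check.n_cases,
                int(check.passed),
            ],
        }
    ).to_csv(out / "derivation_report.tsv", sep="\t", index=False)
    log.info(
        "phenotype: included=%d cases=%d thresholds_passed=%s",
        dreport.included,
        check.n_cases,
        check.passed,
    )


def _stage_qc(cfg: dict, out: Path, seed: int) -> None:
    store = GenotypeStore.from_bed(out / "genotypes")
    kept = qc_filter(store, **cfg["qc"])
    rep = store.variants[["id", "maf", "missing_rate"]].copy()
    rep["kept"] = 0
    rep.loc[kept, "kept"] = 1
    rep.to_csv(out / "qc_report.tsv", sep="\t", index=False, float_format="%.8g")
    log.info("qc: kept %d / %d variants", len(kept), store.n_variants)


def _stage_fit(cfg: dict, out: Path, seed: int) -> None:
    store = GenotypeStore.from_bed(out / "genotypes")
    pheno = ProgressionDataset.from_tsv(out / "phenotype.tsv")
    qc = pd.read_csv(out / "qc_report.tsv", sep="\t")
    kept = np.flatnonzero(qc["kept"].to_numpy())
    fit_kwargs = dict(cfg["fit"])
    fit_kwargs.setdefault("split_seed", seed)
    config = _basil.BasilConfig(**fit_kwargs)
    rows = pd.Series(np.arange(store.n_individuals), index=store.sample_ids)
    row_idx = rows.loc[pheno.person_ids].to_numpy()
    if not np.array_equal(row_idx, np.arange(store.n_individuals)):
        raise ValueError("phenotype persons must match the genotype store rows")
    splits = _basil.make_split(len(pheno), config, status=pheno.status)
    stats = impute_and_standardize(store, kept, splits[0])
    source = _basil.GenotypeSource(store, stats)
    path, splits = _basil.basil_fit(
        pheno.y, pheno.status, pheno.covariate_matrix(), source, config, splits=splits
    )
    model = _basil.select_model(
        path,
        source,
        train_person_ids=pheno.person_ids[splits[0]],
        covariate_names=list(pheno.covariates.columns),
    )
    path.summary().to_csv(out / "path_summary.tsv", sep="\t", index=False, float_format="%.10g")
    path.coefficients_long(source.variant_ids).to_csv(
        out / "path_coefficients.tsv", sep="\t", index=False, float_format="%.10g"
    )
    model.to_tsv(out / "model.tsv")
    split_df = pd.DataFrame(
        {
            "person_id": pheno.person_ids,
            "split": np.select(
                [
                    np.isin(np.arange(len(pheno)), splits[0]),
                    np.isin(np.arange(len(pheno)), splits[1]),
                ],
                ["train", "val"],
                default="test",
            ),
        }
    )
    split_df.to_csv(out / "splits.tsv", sep="\t", index=False)
    log.info(
        "fit: path length %d, selected lambda %.5g with %d active variants "
        "(validation C=%.4f), %d screening iterations",
        len(path),
        model.selected_lambda,
        model.n_active,
        model.validation_c_index,
        path.n_basil_iter,
    )


def _stage_evaluate(cfg: dict, out: Path, seed: int) -> None:
    store = GenotypeStore.from_bed(out / "genotypes")
    pheno = ProgressionDataset.from_tsv(out / "phenotype.tsv")
    splits = pd.read_csv(out / "splits.tsv", sep="\t")
    test_ids = splits.loc[splits["split"] == "test", "person_id"].to_numpy()
    train_ids = splits.loc[splits["split"] == "train", "person_id"].to_numpy()
    model = _basil.PHSModel.from_tsv(out / "model.tsv", train_person_ids=train_ids)
    mask = np.isin(pheno.person_ids, test_ids)
    cohort = ProgressionDataset(
        person_ids=pheno.person_ids[mask],
        y=pheno.y[mask],
        status=pheno.status[mask],
        covariates=pheno.covariates.loc[mask],
        name="test",
    )
    ecfg = cfg["evaluate"]
    report = evaluate(
        model,
        cohort,
        store,
        horizons=tuple(ecfg["horizons"]),
        adjusted=bool(ecfg["adjusted"]),
    )
    report.summary().to_csv(
        out / "evaluation_summary.tsv", sep="\t", index=False, float_format="%.8g"
    )
    report.km_long().to_csv(out / "km_curves.tsv", sep="\t", index=False, float_format="%.8g")
    log.info(
        "evaluate: n=%d cases=%d scale HR=%.3f (p=%.3g) C=%.4f",
        report.n,
        report.n_cases,
        report.scale.hr,
        report.scale.p,
        report.c_index,
    )


_RUNNERS = {
    "simulate": _stage_simulate,
    "phenotype": _stage_phenotype,
    "qc": _stage_qc,
    "fit": _stage_fit,
    "evaluate": _stage_evaluate,
}
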