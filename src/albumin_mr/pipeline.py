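"""Config-driven orchestration of the full analysis.

Composes the stages in the order the analysis reports them: cohort
derivation and descriptives, SNP QC plus the hypoalbuminemia association
scan, OLS / 2SLS / Durbin-Wu-Hausman for the blood-pressure-change
outcomes, Cox models with Kaplan-Meier / log-rank / proportional-hazards
diagnostics, the two-stage residual-inclusion causal hazard ratio, and
the restricted-cubic-spline curves.  Every artifact is a TSV with a
header; a JSON manifest records the seed, a config hash and per-stage row
counts.  A single global seed is fanned out to per-stage child seeds by
hashing the stage name, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort_core
from . import instrumental_variable as iv
from .genetic_association import (
    GenotypeMatrix,
    QCThresholds,
    association_frame,
    encode_genetic_model,
    genomic_inflation_factor,
    logistic_association_scan,
    qc_report_frame,
    qq_manhattan_tables,
    read_genotypes,
    snp_qc,
)
from .rcs import curve_frame, fit_rcs_cox, fit_rcs_linear, nonlinearity_test
from .survival_models import (
    MODEL_I,
    MODEL_II,
    MODEL_III,
    SurvivalData,
    adjusted_survival_curves,
    fit_cox,
    kaplan_meier,
    log_rank_test,
    ph_supremum_test,
)
from .synthetic_cohort import SimulationConfig, generate_cohort

log = logging.getLogger("albumin_mr")

GENETIC_MODELS = ("additive", "dominant", "recessive")


@dataclass
class RunConfig:
    """Exactly one of (phenotype_path, genotype_path) or simulation."""

    out_dir: str | Path = "albumin_mr_out"
    seed: int = 0
    phenotype_path: str | None = None
    genotype_path: str | None = None
    genotype_format: str = "tsv-dosage"
    simulation: SimulationConfig | None = None
    run_gwas: bool = True
    run_iv: bool = True
    run_survival: bool = True
    run_rcs: bool = True
    qc: QCThresholds = field(default_factory=QCThresholds)
    cohort: cohort_core.CohortConfig = field(default_factory=cohort_core.CohortConfig)
    instrument_snps: list[str] | None = None   # default: QC-passing iv_snp_*
    iv_coding: str = "dominant"
    ph_test_resamples: int = 200

    def __post_init__(self) -> None:
        has_files = self.phenotype_path is not None and self.genotype_path is not None
        if has_files == (self.simulation is not None):
            raise ValueError(
                "provide either input paths or a simulation block, not both"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        qc = raw.pop("qc", None)
        cohort = raw.pop("cohort", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim else None,
            qc=QCThresholds(**qc) if qc else QCThresholds(),
            cohort=cohort_core.CohortConfig(**cohort) if cohort else cohort_core.CohortConfig(),
            **raw,
        )
        return cfg

    def config_hash(self) -> str:
        payload = {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        payload["out_dir"] = None  # location does not change the analysis
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage; returns (and writes) the run manifest."""
    t0 = _time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    # ---- input data -------------------------------------------------------
    if config.simulation is not None:
        sim_dir = out / "simulated"
        generate_cohort(config.simulation, sim_dir)
        phenotype_path = sim_dir / "phenotype.tsv"
        genotype_path = sim_dir / "genotypes.tsv"
        genotype_format = "tsv-dosage"
        record("simulate", n_subjects=config.simulation.n_subjects)
        manifest["outputs"] += [str(phenotype_path), str(genotype_path)]
    else:
        phenotype_path = Path(config.phenotype_path)
        genotype_path = Path(config.genotype_path)
        genotype_format = config.genotype_format

    baseline, visits = cohort_core.read_phenotype_table(phenotype_path)
    genotypes = read_genotypes(genotype_path, genotype_format)

    # ---- eligibility + derived variables + descriptives -------------------
    eligible, exclusion_log = cohort_core.apply_eligibility_filter(baseline)
    cohort = cohort_core.derive_cohort(eligible, visits, config.cohort)
    cohort["sex_male"] = (cohort["sex"] == "male").astype(float)
    (out / "exclusion_log.json").write_text(json.dumps(exclusion_log, indent=1))
    n = _write(cohort, out / "cohort.tsv")
    manifest["outputs"] += [str(out / "exclusion_log.json"), str(out / "cohort.tsv")]
    record(
        "cohort",
        n_input=len(baseline),
        n_excluded=len(exclusion_log),
        n_analysis=n,
        n_events=int(cohort["event"].sum()),
    )

    desc_vars = [
        c
        for c in cohort.columns
        if c
        not in {
            "subject_id", "sex", "hypoalbuminemia", "event", "event_month",
            "prevalent_htn", "diabetes", "ckd", "cvd", "malignancy", "med_flag",
        }
        and pd.api.types.is_numeric_dtype(cohort[c])
    ]
    table1 = cohort_core.summarize_baseline(
        cohort.assign(hypoalbuminemia=cohort["hypoalbuminemia"].astype(float)),
        variables=desc_vars,
    )
    _write(table1, out / "baseline_table.tsv")
    manifest["outputs"].append(str(out / "baseline_table.tsv"))
    record("descriptives", n_variables=len(table1))

    # align genotype rows to the analysis cohort
    order = {sid: i for i, sid in enumerate(genotypes.subject_ids)}
    missing_geno = [s for s in cohort["subject_id"] if s not in order]
    if missing_geno:
        raise ValueError(
            f"{len(missing_geno)} cohort subjects lack genotypes, e.g. "
            f"{missing_geno[:3]}"
        )
    rows = np.array([order[s] for s in cohort["subject_id"]])
    aligned = GenotypeMatrix(
        subject_ids=genotypes.subject_ids[rows],
        snp_ids=genotypes.snp_ids,
        dosage=genotypes.dosage[rows],
        metadata=genotypes.metadata,
    )

    qc_records = snp_qc(aligned, config.qc)
    _write(qc_report_frame(qc_records), out / "snp_qc.tsv")
    manifest["outputs"].append(str(out / "snp_qc.tsv"))
    passing = {r.snp_id for r in qc_records if r.passed}
    record("snp_qc", n_snps=len(qc_records), n_pass=len(passing))

    instruments = config.instrument_snps or [
        s for s in aligned.snp_ids if str(s).startswith("iv_snp")
    ]
    instruments = [s for s in instruments if s in passing]

    covar_age_sex = cohort[["age", "sex_male"]].to_numpy(float)

    # ---- GWAS scan --------------------------------------------------------
    if config.run_gwas:
        keep_idx = [i for i, s in enumerate(aligned.snp_ids) if s in passing]
        scan_matrix = GenotypeMatrix(
            aligned.subject_ids,
            aligned.snp_ids[keep_idx],
            aligned.dosage[:, keep_idx],
            metadata=aligned.metadata,
        )
        phen = cohort["hypoalbuminemia"].astype(float).to_numpy()
        results = logistic_association_scan(scan_matrix, phen, covar_age_sex)
        assoc = association_frame(results)
        _write(assoc, out / "association_scan.tsv")
        qq, man = qq_manhattan_tables(results, aligned.metadata)
        _write(qq, out / "qq_table.tsv")
        _write(man, out / "manhattan_table.tsv")
        manifest["outputs"] += [
            str(out / "association_scan.tsv"),
            str(out / "qq_table.tsv"),
            str(out / "manhattan_table.tsv"),
        ]
        p_add = assoc["p_additive"].to_numpy(float)
        lam = (
            genomic_inflation_factor(p_values=p_add[np.isfinite(p_add)])
            if np.isfinite(p_add).sum() >= 10
            else np.nan
        )
        record("gwas", n_snps=len(results), **{"lambda": None if np.isnan(lam) else lam})

    # ---- IV: OLS / 2SLS / DWH on the BP-change outcomes -------------------
    if config.run_iv:
        rows_iv = []
        for outcome_name in ("delta_sbp", "delta_dbp"):
            sub = cohort.dropna(subset=[outcome_name, "albumin", "age"])
            y = sub[outcome_name].to_numpy(float)
            x = sub["albumin"].to_numpy(float)
            C = sub[["age", "sex_male"]].to_numpy(float)
            ols = iv.fit_ols(y, x, C, covariate_set="age+sex")
            rows_iv.append(
                {
                    "outcome": outcome_name, "estimator": "ols",
                    "instrument": "", "beta": ols.beta, "se": ols.se,
                    "p": ols.p, "first_stage_F": np.nan, "dwh_p": np.nan,
                    "n": ols.n,
                }
            )
            sub_rows = np.array([order[s] for s in sub["subject_id"]])
            for snp in instruments:
                dosage = genotypes.dosage[sub_rows, list(genotypes.snp_ids).index(snp)]
                z = encode_genetic_model(dosage, config.iv_coding)
                ok = np.isfinite(z)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", iv.WeakInstrumentWarning)
                    est = iv.fit_2sls(y[ok], x[ok], z[ok], C[ok],
                                      covariate_set="age+sex")
                _, dwh_p = iv.dwh_test(y[ok], x[ok], z[ok], C[ok])
                rows_iv.append(
                    {
                        "outcome": outcome_name, "estimator": "tsls",
                        "instrument": snp, "beta": est.beta, "se": est.se,
                        "p": est.p, "first_stage_F": est.first_stage_F,
                        "dwh_p": dwh_p, "n": est.n,
                    }
                )
        _write(pd.DataFrame(rows_iv), out / "iv_estimates.tsv")
        manifest["outputs"].append(str(out / "iv_estimates.tsv"))
        record("iv", n_estimates=len(rows_iv))

    # ---- survival ---------------------------------------------------------
    if config.run_survival or config.run_rcs:
        surv = cohort[cohort["event_month"] > 0].copy()
        surv["albumin_f"] = surv["albumin"].astype(float)
    if config.run_survival:
        model_sets = {"model1": MODEL_I, "model2": MODEL_II, "model3": MODEL_III}
        rows_cox = []
        tsri_rows = []
        for name, covs in model_sets.items():
            covs_avail = [c for c in covs if c in surv.columns]
            # albumin as the exposure of interest (Models I-II; III adjusts it)
            fit_vars = (
                covs_avail if "albumin" in covs_avail else ["albumin"] + covs_avail
            )
            sub = surv.dropna(subset=fit_vars)
            data = SurvivalData.from_frame(sub, "event_month", "event", fit_vars)
            fit = fit_cox(data)
            summ = fit.summary()
            summ.insert(0, "model", name)
            summ.insert(1, "exposure", "albumin")
            rows_cox.append(summ)
            for snp in instruments:
                snp_col = genotypes.dosage[
                    np.array([order[s] for s in sub["subject_id"]]),
                    list(genotypes.snp_ids).index(snp),
                ]
                for gmodel in GENETIC_MODELS:
                    zz = encode_genetic_model(snp_col, gmodel)
                    okz = np.isfinite(zz)
                    frame = sub.loc[okz, covs_avail].astype(float)
                    frame.insert(0, f"{snp}_{gmodel}", zz[okz])
                    try:
                        gfit = fit_cox(
                            SurvivalData(
                                sub.loc[okz, "event_month"].to_numpy(float),
                                sub.loc[okz, "event"].to_numpy(bool),
                                frame.reset_index(drop=True),
                            )
                        )
                    except Exception as exc:  # monomorphic/divergent codings
                        log.warning("cox %s %s %s failed: %s", name, snp, gmodel, exc)
                        continue
                    gsumm = gfit.summary().iloc[:1].copy()
                    gsumm.insert(0, "model", name)
                    gsumm.insert(1, "exposure", f"{snp} ({gmodel})")
                    rows_cox.append(gsumm)
        cox_table = pd.concat(rows_cox, ignore_index=True)
        _write(cox_table, out / "cox_models.tsv")
        manifest["outputs"].append(str(out / "cox_models.tsv"))

        # KM + log-rank by hypoalbuminemia
        km = kaplan_meier(
            surv["event_month"].to_numpy(float),
            surv["event"].to_numpy(bool),
            surv["hypoalbuminemia"].astype(int).to_numpy(),
        )
        km_rows = []
        for lev, curve in km.items():
            km_rows.append(
                pd.DataFrame(
                    {
                        "group": lev,
                        "time": curve.times,
                        "survival": curve.survival,
                        "at_risk": curve.at_risk,
                        "n_events": curve.n_events,
                        "greenwood_var": curve.greenwood_var,
                    }
                )
            )
        _write(pd.concat(km_rows, ignore_index=True), out / "km_curves.tsv")
        chi2, df_lr, p_lr = log_rank_test(
            surv["event_month"], surv["event"].astype(bool),
            surv["hypoalbuminemia"].astype(int),
        )
        _write(
            pd.DataFrame(
                [{"comparison": "hypoalbuminemia", "chi2": chi2, "df": df_lr, "p": p_lr}]
            ),
            out / "logrank.tsv",
        )
        manifest["outputs"] += [str(out / "km_curves.tsv"), str(out / "logrank.tsv")]

        # PH supremum diagnostics + adjusted curves on the Model I albumin fit
        m1_vars = ["albumin"] + [c for c in MODEL_I if c in surv.columns]
        sub1 = surv.dropna(subset=m1_vars)
        data1 = SurvivalData.from_frame(sub1, "event_month", "event", m1_vars)
        fit1 = fit_cox(data1)
        ph = ph_supremum_test(
            fit1, data1, n_resample=config.ph_test_resamples,
            seed=stage_seed(config.seed, "ph-test"),
        )
        _write(ph, out / "ph_supremum.tsv")
        curves = adjusted_survival_curves(
            fit1,
            {"albumin_le_4.0": {"albumin": 3.9}, "albumin_gt_4.0": {"albumin": 4.4}},
        )
        _write(curves, out / "adjusted_survival.tsv")
        manifest["outputs"] += [
            str(out / "ph_supremum.tsv"),
            str(out / "adjusted_survival.tsv"),
        ]

        # 2SRI causal hazard ratios
        for snp in instruments:
            for name, covs in (("model1", MODEL_I), ("model2", MODEL_II)):
                covs_avail = [c for c in covs if c in surv.columns]
                sub = surv.dropna(subset=["albumin"] + covs_avail)
                snp_col = genotypes.dosage[
                    np.array([order[s] for s in sub["subject_id"]]),
                    list(genotypes.snp_ids).index(snp),
                ]
                z = encode_genetic_model(snp_col, config.iv_coding)
                okz = np.isfinite(z)
                try:
                    tsri = iv.fit_2sri_cox(
                        sub.loc[okz, "event_month"].to_numpy(float),
                        sub.loc[okz, "event"].to_numpy(bool),
                        sub.loc[okz, "albumin"].to_numpy(float),
                        z[okz],
                        sub.loc[okz, covs_avail].astype(float),
                    )
                except Exception as exc:
                    log.warning("2sri %s %s failed: %s", snp, name, exc)
                    continue
                tsri_rows.append(
                    {
                        "instrument": snp, "coding": config.iv_coding,
                        "model": name, "hr": tsri.hr,
                        "ci_lower": tsri.ci[0], "ci_upper": tsri.ci[1],
                        "log_hr": tsri.log_hr, "se": tsri.se, "p": tsri.p,
                        "resid_p": tsri.resid_p,
                        "first_stage_F": tsri.first_stage_F,
                        "ci_method": tsri.ci_method, "n": tsri.n,
                    }
                )
        _write(pd.DataFrame(tsri_rows), out / "tsri_causal_hr.tsv")
        manifest["outputs"].append(str(out / "tsri_causal_hr.tsv"))
        record(
            "survival",
            n_cox_rows=len(cox_table),
            logrank_p=p_lr,
            n_tsri=len(tsri_rows),
        )

    # ---- restricted cubic splines ----------------------------------------
    if config.run_rcs:
        rcs_outputs = {}
        for outcome_name in ("delta_sbp", "delta_dbp"):
            sub = cohort.dropna(subset=[outcome_name, "albumin", "age", "smoker"])
            curve = fit_rcs_linear(
                sub[outcome_name].to_numpy(float),
                sub["albumin"].to_numpy(float),
                sub[["age", "sex_male", "smoker"]].to_numpy(float),
                reference=4.0,
            )
            rcs_outputs[f"rcs_{outcome_name}"] = curve
        covs2 = [c for c in MODEL_II if c in surv.columns]
        sub = surv.dropna(subset=["albumin"] + covs2)
        cox_curve = fit_rcs_cox(
            sub["event_month"].to_numpy(float),
            sub["event"].to_numpy(bool),
            sub["albumin"].to_numpy(float),
            sub[covs2].astype(float),
            reference=4.0,
        )
        rcs_outputs["rcs_hazard_ratio"] = cox_curve
        nl_rows = []
        for tag, curve in rcs_outputs.items():
            _write(curve_frame(curve), out / f"{tag}.tsv")
            manifest["outputs"].append(str(out / f"{tag}.tsv"))
            stat, dfree, p = nonlinearity_test(curve)
            nl_rows.append({"curve": tag, "wald": stat, "df": dfree, "p": p})
        _write(pd.DataFrame(nl_rows), out / "nonlinearity_tests.tsv")
        manifest["outputs"].append(str(out / "nonlinearity_tests.tsv"))
        record("rcs", n_curves=len(rcs_outputs))

    manifest["runtime_s"] = round(_time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
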