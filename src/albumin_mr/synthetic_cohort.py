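"""Synthetic biennial-visit cohorts with known causal ground truth.

Generates cohorts carrying the statistical structure the downstream
analysis assumes: instrument SNPs that shift serum albumin, an unobserved
confounder U acting on both albumin and the hypertension hazard (and on
blood-pressure drift), a latent exponential time-to-hypertension, and a
visit grid on which hypertension is *detected* (BP >= 140/90 or
antihypertensive medication at a scheduled exam).  A panel of null SNPs,
independent of every phenotype, supports QQ-plot / genomic-inflation
calibration.

Ground truth (the confounder realizations, latent onset times and the
generating coefficients) is returned as a separate sidecar object and
written to its own JSON file, so pipeline stages can never read it.

Default parameters emulate the published cohort's margins: n = 4,325
subjects, mean age 49.5 (SD 8.2), 45.3% male, 25.8% smokers, serum albumin
centred so that ~27% of subjects fall at or below the 4.0 g/dL
hypoalbuminemia cutoff, biennial exams over 12 years, and an instrument
strength in the first-stage F ~ 16 regime.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_association import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_exposure",
    "simulate_followup",
    "generate_cohort",
    "expected_ols_bias",
]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_subjects: int = 4325
    seed: int = 2021

    # instruments
    n_instruments: int = 2
    maf_instrument: float = 0.30
    a_g: float = -0.030          # g/dL per minor allele (each instrument)
    n_null_snps: int = 0

    # exposure (serum albumin, g/dL)
    albumin_mean: float = 4.185
    albumin_noise_sd: float = 0.25
    age_effect_albumin: float = -0.007   # per year, centred at mean age
    female_effect_albumin: float = -0.05
    smoker_effect_albumin: float = -0.02

    # unobserved confounder U ~ N(0, 1)
    c_u: float = 0.15            # U -> albumin, g/dL per unit U
    d_loghaz: float = 0.10       # U -> log hazard per unit U
    d_bp: float = 0.02           # U -> SBP slope, mmHg/month per unit U
    d_bp_dbp: float = 0.03       # U -> DBP slope (confounded, non-causal path)

    # causal effects of albumin
    b_alb: float = math.log(0.75)  # log-hazard per g/dL
    b_bp: float = -0.05            # SBP slope, mmHg/month per g/dL
    b_bp_dbp: float = 0.0          # DBP slope: no causal effect by default

    # time-to-hypertension (exponential baseline by default)
    baseline_hazard: float = 0.002   # per month; targets ~25% incidence
    weibull_shape: float = 1.0       # 1.0 = exponential
    age_effect_loghaz: float = 0.02
    male_effect_loghaz: float = 0.20
    smoker_effect_loghaz: float = 0.15

    # visit grid and blood-pressure trajectories
    visit_interval_months: float = 24.0
    max_followup_months: float = 144.0
    bp_noise_sd: float = 4.0        # three-reading exam average, mmHg
    bp_slope_sd: float = 0.05       # subject slope heterogeneity, mmHg/month
    sbp_slope_mean: float = 0.05
    dbp_slope_mean: float = 0.03
    sbp_baseline_mean: float = 113.4
    sbp_baseline_sd: float = 10.8
    dbp_baseline_mean: float = 76.0
    dbp_baseline_sd: float = 7.3
    med_uptake_prob: float = 0.3    # treated from first post-onset visit

    # demographics (echoing the source cohort's margins)
    age_mean: float = 49.5
    age_sd: float = 8.2
    male_frac: float = 0.453
    smoker_frac: float = 0.258

    # realism knobs for the eligibility filter
    prevalent_disease_frac: float = 0.02
    missing_albumin_frac: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_instrument <= 0.5):
            raise ValueError("maf_instrument must lie in (0, 0.5]")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.albumin_noise_sd < 0 or self.bp_noise_sd < 0 or self.bp_slope_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.visit_interval_months <= 0:
            raise ValueError("visit interval must be positive")
        if self.baseline_hazard < 0 or not np.isfinite(self.baseline_hazard):
            raise ValueError("baseline hazard must be finite and non-negative")
        if self.weibull_shape <= 0:
            raise ValueError("weibull shape must be positive")

    def instrument_ids(self) -> list[str]:
        return [f"iv_snp_{i + 1}" for i in range(self.n_instruments)]

    def visit_months(self) -> np.ndarray:
        return np.arange(
            0.0,
            self.max_followup_months + 1e-9,
            self.visit_interval_months,
        )

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stream generator derived from the config seed."""
        ss = np.random.SeedSequence(
            [self.seed, int.from_bytes(stream.encode(), "little") % (2**31)]
        )
        return np.random.default_rng(ss)


@dataclass
class SyntheticTruth:
    """Ground truth withheld from the emitted cohort files."""

    config: SimulationConfig
    u: np.ndarray = field(default=None)                 # confounder per subject
    albumin: np.ndarray = field(default=None)
    latent_onset_month: np.ndarray = field(default=None)   # inf if never
    event_latent: np.ndarray = field(default=None)         # onset <= max follow-up
    time_latent: np.ndarray = field(default=None)          # min(onset, max fup)

    def to_json(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "u": self.u.tolist(),
            "albumin": self.albumin.tolist(),
            "latent_onset_month": [
                None if not np.isfinite(t) else t for t in self.latent_onset_month
            ],
            "event_latent": self.event_latent.astype(int).tolist(),
            "time_latent": self.time_latent.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        cfg = SimulationConfig(**raw["config"])
        onset = np.array(
            [np.inf if t is None else t for t in raw["latent_onset_month"]]
        )
        return cls(
            config=cfg,
            u=np.asarray(raw["u"], dtype=float),
            albumin=np.asarray(raw["albumin"], dtype=float),
            latent_onset_month=onset,
            event_latent=np.asarray(raw["event_latent"], dtype=bool),
            time_latent=np.asarray(raw["time_latent"], dtype=float),
        )


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Instrument + null-panel dosages drawn as Binomial(2, MAF) under HWE.

    Null-panel MAFs are drawn uniformly on (0.05, 0.5) so that generated
    SNPs pass the default QC bounds; null SNPs are independent of every
    phenotype by construction.
    """
    rng = config.rng("genotypes")
    n = config.n_subjects
    ids, cols, metadata = [], [], []
    for i, snp in enumerate(config.instrument_ids()):
        ids.append(snp)
        cols.append(rng.binomial(2, config.maf_instrument, size=n).astype(float))
        metadata.append({"snp_id": snp, "chrom": 9, "pos": 10_000 + i * 5_000,
                         "ref": "G", "alt": "A"})
    if config.n_null_snps:
        mafs = rng.uniform(0.05, 0.5, size=config.n_null_snps)
        null = rng.binomial(2, mafs[None, :], size=(n, config.n_null_snps))
        for j in range(config.n_null_snps):
            snp = f"null_{j + 1:06d}"
            ids.append(snp)
            metadata.append(
                {"snp_id": snp, "chrom": int(j % 22) + 1, "pos": 1_000 + j,
                 "ref": "A", "alt": "C"}
            )
        cols.append(null.astype(float))
    dosage = np.column_stack(cols)
    subject_ids = np.array([f"S{i + 1:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(
        subject_ids=subject_ids,
        snp_ids=np.asarray(ids, dtype=object),
        dosage=dosage,
        metadata=pd.DataFrame(metadata).set_index("snp_id"),
    )


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Baseline demographics and labs, independent of genotype and U."""
    rng = config.rng("covariates")
    n = config.n_subjects
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:05d}" for i in range(n)],
            "age": rng.normal(config.age_mean, config.age_sd, n).round(1),
            "sex": np.where(rng.random(n) < config.male_frac, "male", "female"),
            "smoker": (rng.random(n) < config.smoker_frac).astype(int),
            "bmi": rng.normal(24.0, 3.1, n).round(1),
            "waist": rng.normal(80.4, 8.5, n).round(1),
            "hemoglobin": rng.normal(13.4, 1.5, n).round(1),
            "platelet": rng.normal(262.0, 61.5, n).round(0),
            "hba1c": rng.normal(5.5, 0.34, n).round(2),
            "alt": np.exp(rng.normal(np.log(22.0), 0.45, n)).round(1),
            "ggt": np.exp(rng.normal(np.log(22.0), 0.6, n)).round(1),
            "triglyceride": np.exp(rng.normal(np.log(120.0), 0.5, n)).round(0),
            "hdl": rng.normal(45.2, 10.0, n).round(1),
            "creatinine": np.where(
                rng.random(n) < config.male_frac,  # rough sex-linked shift
                rng.normal(0.95, 0.14, n),
                rng.normal(0.75, 0.12, n),
            ).round(2),
        }
    )
    df["creatinine"] = df["creatinine"].clip(lower=0.3)
    return df


def simulate_exposure(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Serum albumin from the first-stage model.

    albumin = mean + a_g * sum(G_instr) + covariate effects + c_u * U + noise
    with U ~ N(0, 1).  Returns (albumin, U); U belongs in SyntheticTruth.
    """
    if genotypes.n_subjects != len(covariates):
        raise ValueError("genotype and covariate row counts differ")
    rng = config.rng("exposure")
    n = genotypes.n_subjects
    u = rng.standard_normal(n)
    g_sum = np.zeros(n)
    for snp in config.instrument_ids():
        if snp in list(genotypes.snp_ids):
            g_sum += np.nan_to_num(genotypes.column(snp))
    # centred so albumin_mean is the marginal population mean
    g_centre = 2.0 * config.n_instruments * config.maf_instrument
    albumin = (
        config.albumin_mean
        + config.a_g * (g_sum - g_centre)
        + config.age_effect_albumin * (covariates["age"].to_numpy() - config.age_mean)
        + config.female_effect_albumin
        * ((covariates["sex"].to_numpy() == "female") - (1.0 - config.male_frac))
        + config.smoker_effect_albumin
        * (covariates["smoker"].to_numpy() - config.smoker_frac)
        + config.c_u * u
        + rng.standard_normal(n) * config.albumin_noise_sd
    )
    return albumin, u


def _log_hazard(
    albumin: np.ndarray, u: np.ndarray, covariates: pd.DataFrame,
    config: SimulationConfig,
) -> np.ndarray:
    return (
        config.b_alb * (albumin - config.albumin_mean)
        + config.d_loghaz * u
        + config.age_effect_loghaz * (covariates["age"].to_numpy() - config.age_mean)
        + config.male_effect_loghaz * (covariates["sex"].to_numpy() == "male")
        + config.smoker_effect_loghaz * covariates["smoker"].to_numpy()
    )


def simulate_followup(
    exposure: np.ndarray,
    u: np.ndarray,
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Latent hypertension onset plus the visit-grid records that reveal it.

    Onset times follow a proportional-hazards model with Weibull baseline
    (exponential when shape = 1).  Blood pressure drifts linearly per
    subject; after latent onset the emitted visit BP crosses the 140/90
    threshold, so the detection rule fires at the first post-onset visit.
    Censoring is administrative at the end of follow-up.
    """
    albumin = np.asarray(exposure, dtype=float)
    if not np.all(np.isfinite(albumin)):
        raise ValueError("exposure must be finite")
    rng = config.rng("followup")
    n = len(albumin)
    log_rel = _log_hazard(albumin, u, covariates, config)
    if not np.all(np.isfinite(log_rel)):
        raise ValueError("non-finite hazard; check simulation parameters")
    h = config.baseline_hazard * np.exp(log_rel)
    # inverse-transform Weibull PH draw; shape 1 reduces to exponential
    e = rng.exponential(1.0, n)
    with np.errstate(divide="ignore"):
        onset = np.where(h > 0, (e / h) ** (1.0 / config.weibull_shape), np.inf)

    months = config.visit_months()
    age = covariates["age"].to_numpy()

    def _baseline_bp(mean, sd, upper):
        a = (50.0 - mean) / sd  # invariant floor for plausible BP
        b = (upper - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)

    sbp0 = _baseline_bp(config.sbp_baseline_mean, config.sbp_baseline_sd, 139.0)
    dbp0 = _baseline_bp(config.dbp_baseline_mean, config.dbp_baseline_sd, 89.0)
    slope_noise = rng.standard_normal(n) * config.bp_slope_sd
    sbp_slope = (
        config.sbp_slope_mean
        + config.b_bp * (albumin - config.albumin_mean)
        + config.d_bp * u
        + slope_noise
    )
    dbp_slope = (
        config.dbp_slope_mean
        + config.b_bp_dbp * (albumin - config.albumin_mean)
        + config.d_bp_dbp * u
        + 0.6 * slope_noise
    )
    on_med = rng.random(n) < config.med_uptake_prob

    rows = []
    subject_ids = covariates["subject_id"].to_numpy()
    for k, month in enumerate(months):
        sbp = sbp0 + sbp_slope * month + rng.standard_normal(n) * config.bp_noise_sd
        dbp = dbp0 + dbp_slope * month + rng.standard_normal(n) * config.bp_noise_sd
        post = month >= onset
        if month > 0:
            # hypertensive BP from the first post-onset exam onward
            bump_s = 140.0 + np.abs(rng.normal(3.0, 4.0, n))
            bump_d = 90.0 + np.abs(rng.normal(2.0, 3.0, n))
            sbp = np.where(post, np.maximum(sbp, bump_s), np.minimum(sbp, 139.4))
            dbp = np.where(post, np.maximum(dbp, bump_d), np.minimum(dbp, 89.4))
        med = post & on_med & (month > 0)
        # physiologic floor/ceiling; the phenotype reader rejects BP
        # outside (50, 300)
        sbp = np.clip(sbp, 60.0, 299.0)
        dbp = np.clip(dbp, 50.5, 299.0)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids,
                    "visit_month": month,
                    "sbp": np.round(sbp, 1),
                    "dbp": np.round(dbp, 1),
                    "med_flag": med.astype(int),
                }
            )
        )
    visits = pd.concat(rows, ignore_index=True)
    visits = visits.sort_values(["subject_id", "visit_month"], kind="mergesort")
    visits = visits.reset_index(drop=True)

    truth = SyntheticTruth(
        config=config,
        u=u,
        albumin=albumin,
        latent_onset_month=onset,
        event_latent=onset <= config.max_followup_months,
        time_latent=np.minimum(onset, config.max_followup_months),
    )
    return visits, truth


def generate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, GenotypeMatrix, SyntheticTruth]:
    """Full cohort draw; optionally writes phenotype/genotype/truth files.

    The phenotype table is a long TSV (one row per subject-visit) carrying
    baseline covariates and exclusion flags on every row; genotypes go to a
    TSV dosage matrix; truth to a JSON sidecar.
    """
    genotypes = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    albumin, u = simulate_exposure(genotypes, covariates, config)
    visits, truth = simulate_followup(albumin, u, covariates, config)

    rng = config.rng("realism")
    n = config.n_subjects
    baseline = covariates.copy()
    baseline["albumin"] = np.round(albumin, 2)
    if config.missing_albumin_frac > 0:
        drop = rng.random(n) < config.missing_albumin_frac
        baseline.loc[drop, "albumin"] = np.nan
    flags = ["prevalent_htn", "diabetes", "ckd", "cvd", "malignancy"]
    for f in flags:
        baseline[f] = 0
    if config.prevalent_disease_frac > 0:
        sick = rng.random(n) < config.prevalent_disease_frac
        which = rng.integers(0, len(flags), size=n)
        for j, f in enumerate(flags):
            baseline.loc[sick & (which == j), f] = 1

    phenotype = visits.merge(baseline, on="subject_id", how="left")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        phenotype.to_csv(out / "phenotype.tsv", sep="\t", index=False,
                         na_rep="NA", float_format="%.4f")
        genotypes.to_tsv(out / "genotypes.tsv")
        truth.to_json(out / "truth.json")
    return phenotype, genotypes, truth


def expected_ols_bias(
    config: SimulationConfig, var_albumin: float | None = None
) -> float:
    """Probability limit of the confounded OLS slope of the BP-change outcome.

    Omitted-variable-bias closed form for the linear-Gaussian configuration:
    OLS of the BP slope on albumin (adjusting the generated covariates)
    converges to  b_bp + d_bp * c_u * Var(U) / Var(albumin | covariates),
    with Var(U) = 1.  Serves as the oracle for what naive OLS estimates.
    """
    if var_albumin is None:
        var_g = (
            config.n_instruments
            * 2.0 * config.maf_instrument * (1.0 - config.maf_instrument)
            * config.a_g**2
        )
        var_albumin = var_g + config.c_u**2 + config.albumin_noise_sd**2
    if var_albumin <= 0:
        raise ValueError("exposure variance must be positive")
    return config.b_bp + config.d_bp * config.c_u / var_albumin
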