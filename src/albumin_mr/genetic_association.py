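"""SNP quality control and the hypoalbuminemia association scan.

Implements the genotype-side half of the analysis: reading dosage data
(TSV or VCF), per-SNP quality control (call rate, minor allele frequency,
exact Hardy-Weinberg test), a logistic association scan of hypoalbuminemia
under additive / dominant / recessive codings with a per-SNP minimum
p-value, and genome-wide diagnostics (genomic inflation factor lambda,
QQ / Manhattan plot tables).

The scan fits one maximum-likelihood logistic regression per SNP and
genetic model.  Because null-panel calibration requires tens of thousands
of fits, the solver is a batched Newton-Raphson that shares the covariate
block across SNPs and solves all per-SNP (k+1)x(k+1) systems at once; it
is validated against statsmodels' Logit in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

__all__ = [
    "GenotypeMatrix",
    "SNPQCRecord",
    "AssociationResult",
    "QCThresholds",
    "read_genotypes",
    "hwe_exact_test",
    "snp_qc",
    "encode_genetic_model",
    "logistic_association_scan",
    "genomic_inflation_factor",
    "qq_manhattan_tables",
]

# median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

GENETIC_MODELS = ("additive", "dominant", "recessive")


class GenotypeParseError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Dosage matrix (subjects x SNPs) counting minor alleles, NaN = missing."""

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray
    metadata: pd.DataFrame | None = None  # per-SNP chrom/pos/ref/alt

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        idx = list(self.snp_ids).index(snp_id)
        return self.dosage[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.subject_ids, columns=self.snp_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "subject_id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(
            subject_ids=df.index.to_numpy(dtype=object),
            snp_ids=df.columns.to_numpy(dtype=object),
            dosage=df.to_numpy(dtype=float),
        )


@dataclass
class QCThresholds:
    """Inclusion bounds; a SNP passes when it meets every bound (inclusive)."""

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    min_hwe_p: float = 0.001


@dataclass
class SNPQCRecord:
    snp_id: str
    call_rate: float
    maf: float
    hwe_p: float
    passed: bool
    fail_reasons: tuple[str, ...] = ()


@dataclass
class AssociationResult:
    snp_id: str
    beta: dict = field(default_factory=dict)       # model -> log-odds
    se: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)          # model -> Wald p (NaN if flagged)
    flags: dict = field(default_factory=dict)      # model -> failure reason
    min_p: float = np.nan
    best_model: str | None = None
    n_used: dict = field(default_factory=dict)


def read_genotypes(path, fmt: str = "tsv-dosage") -> GenotypeMatrix:
    """Read genotypes from a TSV dosage matrix or a VCF with GT fields.

    Dosages always count the *minor* allele as determined from the observed
    sample frequencies; heterozygotes map to 1 regardless of phase.
    Multi-allelic VCF records are skipped with a warning.
    """
    if fmt == "tsv-dosage":
        return GenotypeMatrix.from_tsv(path)
    if fmt != "vcf":
        raise ValueError(f"unknown genotype format {fmt!r}")

    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path), gts012=True)
    subject_ids = np.asarray(vcf.samples, dtype=object)
    snp_ids, columns, meta = [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic site {variant.CHROM}:{variant.POS}"
            )
            continue
        # gts012: 0/1/2 ALT copies, 3 = missing
        alt_dosage = np.asarray(variant.gt_types, dtype=float)
        alt_dosage[alt_dosage == 3] = np.nan
        with np.errstate(invalid="ignore"):
            alt_freq = np.nanmean(alt_dosage) / 2.0
        if np.isnan(alt_freq):
            dosage = alt_dosage
        elif alt_freq > 0.5:
            dosage = 2.0 - alt_dosage  # REF is the minor allele here
        else:
            dosage = alt_dosage
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(dosage)
        meta.append(
            {
                "snp_id": snp_ids[-1],
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": variant.ALT[0],
            }
        )
    if not snp_ids:
        raise GenotypeParseError(f"no usable bi-allelic sites in {path}")
    return GenotypeMatrix(
        subject_ids=subject_ids,
        snp_ids=np.asarray(snp_ids, dtype=object),
        dosage=np.column_stack(columns),
        metadata=pd.DataFrame(meta).set_index("snp_id"),
    )


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed configuration.  Monomorphic sites have a single attainable
    configuration and return p = 1.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotyped subject is required")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor == 0 or n_major == 0:
        return 1.0

    rare = min(n_minor, n_major)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = k | allele counts) up to a constant:
    # n! / (n_aa! n_ab! n_bb!) * 2^k with n_ab=k, n_bb=(rare-k)/2
    n_hom_rare = (rare - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(n_hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    observed = min(n_het, rare)  # orient to the rarer allele
    p_obs = prob[np.searchsorted(hets, observed)]
    # tolerance guards float ties between equally probable configurations
    p = prob[prob <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _snp_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    obs = dosage[np.isfinite(dosage)]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def snp_qc(
    genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> list[SNPQCRecord]:
    """Per-SNP call rate / MAF / Hardy-Weinberg quality control.

    A SNP passes when call_rate >= 95%, MAF >= 0.05 and exact HWE
    p >= 0.001 (all inclusive); thresholds are configurable.
    """
    if genotypes.n_snps == 0:
        raise ValueError("genotype matrix has no SNPs")
    thr = thresholds or QCThresholds()
    records = []
    for j, snp_id in enumerate(genotypes.snp_ids):
        col = genotypes.dosage[:, j]
        n_obs = int(np.isfinite(col).sum())
        call_rate = n_obs / genotypes.n_subjects
        if n_obs == 0:
            records.append(
                SNPQCRecord(str(snp_id), 0.0, np.nan, np.nan, False, ("call_rate",))
            )
            continue
        n0, n1, n2 = _snp_counts(col)
        freq = (n1 + 2 * n2) / (2 * n_obs)
        maf = min(freq, 1.0 - freq)
        hwe_p = hwe_exact_test(n0, n1, n2)
        reasons = []
        if call_rate < thr.min_call_rate:
            reasons.append("call_rate")
        if maf < thr.min_maf:
            reasons.append("maf")
        if hwe_p < thr.min_hwe_p:
            reasons.append("hwe")
        records.append(
            SNPQCRecord(
                str(snp_id), call_rate, maf, hwe_p, not reasons, tuple(reasons)
            )
        )
    return records


def qc_report_frame(records: list[SNPQCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "call_rate": [r.call_rate for r in records],
            "maf": [r.maf for r in records],
            "hwe_p": [r.hwe_p for r in records],
            "pass": [r.passed for r in records],
            "fail_reasons": [",".join(r.fail_reasons) for r in records],
        }
    )


def encode_genetic_model(dosage: np.ndarray, model: str) -> np.ndarray:
    """Recode minor-allele dosages under a genetic model; NaN propagates."""
    dosage = np.asarray(dosage, dtype=float)
    if model == "additive":
        return dosage.copy()
    if model == "dominant":
        out = (dosage >= 1).astype(float)
    elif model == "recessive":
        out = (dosage == 2).astype(float)
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    out[~np.isfinite(dosage)] = np.nan
    return out


def _batched_logistic(
    y: np.ndarray,
    C: np.ndarray,
    G: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit y ~ C + g_s per column g_s of G, all SNPs at once.

    Missing entries of G are given weight zero (complete-case per SNP).
    Returns (beta_g, se_g, converged) arrays of length G.shape[1].
    """
    n, k = C.shape
    m = G.shape[1]
    mask = np.isfinite(G)
    Gz = np.where(mask, G, 0.0)
    W0 = mask.astype(float)
    # outer products of covariate rows, flattened so the Hessian blocks are
    # plain matmuls: H_cc[s] = sum_i w_is * C_i C_i'
    CC = (C[:, :, None] * C[:, None, :]).reshape(n, k * k)

    def hessian(g: np.ndarray, wt: np.ndarray) -> np.ndarray:
        s = g.shape[1]
        H = np.empty((s, k + 1, k + 1))
        H[:, :k, :k] = (wt.T @ CC).reshape(s, k, k)
        hg = (C.T @ (wt * g)).T
        H[:, :k, k] = hg
        H[:, k, :k] = hg
        H[:, k, k] = np.sum(wt * g * g, axis=0)
        return H

    beta = np.zeros((m, k + 1))
    active = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        b = beta[idx]
        g = Gz[:, idx]
        w0 = W0[:, idx]
        eta = C @ b[:, :k].T + g * b[:, k]
        mu = expit(eta)
        r = (y[:, None] - mu) * w0
        wt = mu * (1.0 - mu) * w0
        grad = np.empty((len(idx), k + 1))
        grad[:, :k] = (C.T @ r).T
        grad[:, k] = np.sum(g * r, axis=0)
        H = hessian(g, wt)
        # ridge keeps near-separated fits solvable; flagged downstream
        H[:, np.arange(k + 1), np.arange(k + 1)] += 1e-10
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(Hs, gs, rcond=None)[0]
                             for Hs, gs in zip(H, grad)])
        np.clip(step, -5.0, 5.0, out=step)
        beta[idx] = b + step
        done = np.max(np.abs(step), axis=1) < tol
        active[idx[done]] = False

    converged = ~active
    # final SE from the observed information at the solution
    eta = C @ beta[:, :k].T + Gz * beta[:, k]
    mu = expit(eta)
    wt = mu * (1.0 - mu) * W0
    H = hessian(Gz, wt)
    se = np.full(m, np.nan)
    try:
        Hinv = np.linalg.inv(H)
        se = np.sqrt(np.maximum(Hinv[:, k, k], 0.0))
    except np.linalg.LinAlgError:
        for i in range(m):
            try:
                se[i] = np.sqrt(np.linalg.inv(H[i])[k, k])
            except np.linalg.LinAlgError:
                pass
    return beta[:, k], se, converged


def logistic_association_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    models: tuple[str, ...] = GENETIC_MODELS,
    chunk_size: int = 2000,
) -> list[AssociationResult]:
    """Per-SNP logistic regression of a binary phenotype under each genetic
    model, with the per-SNP minimum p-value across models.

    The phenotype here is hypoalbuminemia case/control status and the
    conventional covariates are age and sex.  Missing dosages are dropped
    per SNP (complete-case); models that are monomorphic after missingness
    or show separation are flagged and excluded from min-P.
    """
    y = np.asarray(phenotype, dtype=float)
    if not np.isin(y[np.isfinite(y)], (0.0, 1.0)).all():
        raise ValueError("phenotype must be binary 0/1")
    n = genotypes.n_subjects
    if len(y) != n:
        raise ValueError("phenotype length does not match genotype rows")
    if covariates is None:
        C = np.ones((n, 1))
    else:
        Cv = np.asarray(covariates, dtype=float)
        if Cv.ndim == 1:
            Cv = Cv[:, None]
        C = np.column_stack([np.ones(n), Cv])

    results = [AssociationResult(snp_id=str(s)) for s in genotypes.snp_ids]
    for model in models:
        coded = encode_genetic_model(genotypes.dosage, model)
        for s0 in range(0, genotypes.n_snps, chunk_size):
            s1 = min(s0 + chunk_size, genotypes.n_snps)
            G = coded[:, s0:s1]
            beta, se, conv = _batched_logistic(y, C, G)
            mask = np.isfinite(G)
            n_used = mask.sum(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mono = (np.nanmin(G, axis=0) == np.nanmax(G, axis=0)) | (
                    n_used == 0
                )
            good = ~mono & conv & np.isfinite(se) & (np.abs(beta) <= 15)
            with np.errstate(invalid="ignore", divide="ignore"):
                pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
            for j in range(s1 - s0):
                res = results[s0 + j]
                res.n_used[model] = int(n_used[j])
                if mono[j]:
                    res.flags[model] = "monomorphic"
                    res.p[model] = np.nan
                elif not good[j]:
                    res.flags[model] = "separation"
                    res.beta[model] = float(beta[j])
                    res.p[model] = np.nan
                else:
                    res.beta[model] = float(beta[j])
                    res.se[model] = float(se[j])
                    res.p[model] = float(pvals[j])

    for res in results:
        usable = {m: p for m, p in res.p.items() if np.isfinite(p)}
        if usable:
            res.best_model = min(usable, key=usable.get)
            res.min_p = usable[res.best_model]
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"snp_id": r.snp_id, "min_p": r.min_p, "best_model": r.best_model}
        for m in GENETIC_MODELS:
            row[f"beta_{m}"] = r.beta.get(m, np.nan)
            row[f"se_{m}"] = r.se.get(m, np.nan)
            row[f"p_{m}"] = r.p.get(m, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def genomic_inflation_factor(
    p_values: np.ndarray | None = None, chi2_stats: np.ndarray | None = None
) -> float:
    """lambda = median observed chi-square(1 df) statistic / 0.4549364."""
    if chi2_stats is None:
        if p_values is None:
            raise ValueError("provide p_values or chi2_stats")
        p = np.asarray(p_values, dtype=float)
        p = p[np.isfinite(p)]
        chi2_stats = stats.chi2.isf(p, 1)
    chi2_stats = np.asarray(chi2_stats, dtype=float)
    chi2_stats = chi2_stats[np.isfinite(chi2_stats)]
    if chi2_stats.size == 0:
        raise ValueError("no finite statistics")
    return float(np.median(chi2_stats) / CHI2_1_MEDIAN)


def qq_manhattan_tables(
    results: list[AssociationResult],
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready QQ and Manhattan tables (no rendering).

    QQ: sorted observed -log10(min_p) against expected order statistics
    -log10((i - 0.5) / n).  Manhattan: chromosome, position, -log10(min_p);
    positions fall back to the SNP index when no metadata is available.
    """
    if not results:
        raise ValueError("no association results")
    p = np.array([r.min_p for r in results], dtype=float)
    keep = np.isfinite(p)
    p_obs = np.sort(p[keep])
    n = p_obs.size
    qq = pd.DataFrame(
        {
            "expected_neglog10_p": -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1],
            "observed_neglog10_p": -np.log10(p_obs)[::-1],
        }
    )
    ids = [r.snp_id for r in results]
    if metadata is not None and {"chrom", "pos"}.issubset(metadata.columns):
        md = metadata.reindex(ids)
        chrom = md["chrom"].to_numpy()
        pos = md["pos"].to_numpy()
    else:
        chrom = np.ones(len(ids), dtype=int)
        pos = np.arange(1, len(ids) + 1)
    with np.errstate(divide="ignore"):
        man = pd.DataFrame(
            {
                "snp_id": ids,
                "chrom": chrom,
                "pos": pos,
                "neglog10_min_p": -np.log10(p),
            }
        )
    return qq, man
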