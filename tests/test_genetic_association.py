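"""SNP QC, exact Hardy-Weinberg testing, and the three-model scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from albumin_mr.genetic_association import (
    GenotypeMatrix,
    QCThresholds,
    encode_genetic_model,
    genomic_inflation_factor,
    hwe_exact_test,
    logistic_association_scan,
    qq_manhattan_tables,
    read_genotypes,
    snp_qc,
)
from albumin_mr.calibration import hwe_enumeration_oracle, qc_fixture_matrix


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(100, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 100) == 1.0


def test_hwe_all_zero_rejected():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


def test_hwe_against_enumeration_oracle_example():
    got = hwe_exact_test(57, 14, 50)
    want = hwe_enumeration_oracle(57, 14, 50)
    assert got == pytest.approx(want, rel=1e-10)
    assert got < 1e-10  # massive heterozygote deficit


@given(
    n0=st.integers(0, 25), n1=st.integers(0, 25), n2=st.integers(0, 25)
)
@settings(max_examples=150, deadline=None)
def test_hwe_matches_exact_rational_enumeration(n0, n1, n2):
    if n0 + n1 + n2 == 0:
        return
    assert hwe_exact_test(n0, n1, n2) == pytest.approx(
        hwe_enumeration_oracle(n0, n1, n2), abs=1e-12
    )


def test_hwe_symmetric_in_allele_labels():
    assert hwe_exact_test(57, 30, 13) == pytest.approx(
        hwe_exact_test(13, 30, 57), abs=1e-12
    )


# ---------------------------------------------------------------------------
# QC

def test_qc_fixture_counts_and_reasons():
    records = {r.snp_id: r for r in snp_qc(qc_fixture_matrix())}
    assert sum(r.passed for r in records.values()) == 7
    assert records["fail_call_rate"].fail_reasons == ("call_rate",)
    assert records["fail_maf"].fail_reasons == ("maf",)
    assert records["fail_hwe"].fail_reasons == ("hwe",)


def test_qc_boundaries_inclusive():
    # MAF exactly 0.05 passes ("below 0.05" excludes strictly-below only)
    n = 200
    dosage = np.zeros((n, 2))
    dosage[:20, 0] = 1.0          # 20 hets of 200 -> freq 0.05
    dosage[:19, 1] = 1.0          # 19 hets -> freq 0.0475 fails
    gm = GenotypeMatrix(
        np.array([f"S{i}" for i in range(n)], object),
        np.array(["maf_at_threshold", "maf_below"], object),
        dosage,
    )
    rec = {r.snp_id: r for r in snp_qc(gm)}
    assert rec["maf_at_threshold"].maf == pytest.approx(0.05)
    assert "maf" not in rec["maf_at_threshold"].fail_reasons
    assert rec["maf_below"].fail_reasons == ("maf",)


def test_qc_custom_thresholds():
    gm = qc_fixture_matrix()
    records = snp_qc(gm, QCThresholds(min_call_rate=0.9, min_maf=0.01, min_hwe_p=0.0))
    assert sum(r.passed for r in records) == 10


# ---------------------------------------------------------------------------
# model coding

def test_genetic_model_codings():
    d = np.array([0.0, 1.0, 2.0, np.nan])
    np.testing.assert_array_equal(encode_genetic_model(d, "additive")[:3], [0, 1, 2])
    np.testing.assert_array_equal(encode_genetic_model(d, "dominant")[:3], [0, 1, 1])
    np.testing.assert_array_equal(encode_genetic_model(d, "recessive")[:3], [0, 0, 1])
    for model in ("additive", "dominant", "recessive"):
        assert np.isnan(encode_genetic_model(d, model)[3])
    with pytest.raises(ValueError):
        encode_genetic_model(d, "codominant")


# ---------------------------------------------------------------------------
# association scan

def _scan_fixture(n=200, m=4, seed=11):
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, 0.3, (n, m)).astype(float)
    G[rng.random((n, m)) < 0.03] = np.nan
    y = (rng.random(n) < 0.35).astype(float)
    C = np.column_stack([rng.normal(50, 8, n), rng.integers(0, 2, n)])
    gm = GenotypeMatrix(
        np.array([f"S{i}" for i in range(n)], object),
        np.array([f"snp{j}" for j in range(m)], object),
        G,
    )
    return gm, y, C, G


def test_scan_matches_direct_likelihood_maximization():
    """Per-SNP betas, SEs and Wald p agree with statsmodels' independent
    Newton maximization of the logistic likelihood."""
    import statsmodels.api as sm

    gm, y, C, G = _scan_fixture()
    results = logistic_association_scan(gm, y, C)
    for model in ("additive", "dominant", "recessive"):
        coded = encode_genetic_model(G, model)
        for j, res in enumerate(results):
            g = coded[:, j]
            ok = np.isfinite(g)
            X = sm.add_constant(np.column_stack([C[ok], g[ok]]))
            fit = sm.Logit(y[ok], X).fit(disp=0)
            assert res.beta[model] == pytest.approx(fit.params[-1], abs=1e-6)
            assert res.se[model] == pytest.approx(fit.bse[-1], abs=1e-6)
            p_wald = 2 * stats.norm.sf(abs(fit.params[-1] / fit.bse[-1]))
            assert res.p[model] == pytest.approx(p_wald, abs=1e-6)


def test_scan_symmetric_dosage_distribution_gives_zero_beta():
    """A SNP whose dosage distribution is identical among cases and
    controls has score zero at beta = 0, hence MLE exactly 0."""
    counts = [30, 20, 10]  # same 0/1/2 composition in each phenotype group
    dosage = np.concatenate([np.repeat([0.0, 1.0, 2.0], counts)] * 2)
    y = np.r_[np.zeros(60), np.ones(60)]
    gm = GenotypeMatrix(
        np.array([f"S{i}" for i in range(120)], object),
        np.array(["snp0"], object),
        dosage[:, None],
    )
    res = logistic_association_scan(gm, y, covariates=None)[0]
    for model in ("additive", "dominant", "recessive"):
        assert res.beta[model] == pytest.approx(0.0, abs=1e-10)


def test_scan_min_p_consistency():
    gm, y, C, _ = _scan_fixture(seed=12)
    for res in logistic_association_scan(gm, y, C):
        finite = {m: p for m, p in res.p.items() if np.isfinite(p)}
        assert res.min_p == min(finite.values())
        assert res.p[res.best_model] == res.min_p
        assert all(res.min_p <= p for p in finite.values())


def test_scan_monomorphic_model_flagged():
    # no minor-allele homozygotes: the recessive coding is constant
    rng = np.random.default_rng(5)
    dosage = rng.binomial(1, 0.3, 150).astype(float)
    gm = GenotypeMatrix(
        np.array([f"S{i}" for i in range(150)], object),
        np.array(["snp0"], object),
        dosage[:, None],
    )
    y = (rng.random(150) < 0.3).astype(float)
    res = logistic_association_scan(gm, y)[0]
    assert res.flags["recessive"] == "monomorphic"
    assert np.isnan(res.p["recessive"])
    assert np.isfinite(res.min_p)  # additive/dominant still usable


def test_scan_rejects_non_binary_phenotype():
    gm, y, C, _ = _scan_fixture()
    with pytest.raises(ValueError):
        logistic_association_scan(gm, y + 0.5, C)


# ---------------------------------------------------------------------------
# diagnostics

def test_lambda_definition():
    assert genomic_inflation_factor(chi2_stats=np.full(5, 0.4549364231)) == (
        pytest.approx(1.0, abs=1e-6)
    )
    assert genomic_inflation_factor(chi2_stats=np.array([1.0, 2.0, 3.0])) == (
        pytest.approx(4.3963, abs=1e-3)
    )
    with pytest.raises(ValueError):
        genomic_inflation_factor(chi2_stats=np.array([]))


def test_lambda_on_uniform_p_values():
    rng = np.random.default_rng(0)
    lam = genomic_inflation_factor(p_values=rng.random(50_000))
    assert 0.97 <= lam <= 1.03


def test_qq_table_conventions():
    from albumin_mr.genetic_association import AssociationResult

    res = [AssociationResult(snp_id="a", min_p=0.01)]
    qq, man = qq_manhattan_tables(res)
    assert qq["observed_neglog10_p"].iloc[0] == pytest.approx(2.0)
    assert qq["expected_neglog10_p"].iloc[0] == pytest.approx(-np.log10(0.5))
    assert man["neglog10_min_p"].iloc[0] == pytest.approx(2.0)

    res = [
        AssociationResult(snp_id=str(i), min_p=p)
        for i, p in enumerate(np.linspace(0.01, 0.99, 50))
    ]
    qq, _ = qq_manhattan_tables(res)
    n = len(res)
    want = np.sort(-np.log10((np.arange(1, n + 1) - 0.5) / n))[::-1]
    np.testing.assert_allclose(np.sort(qq["expected_neglog10_p"]), np.sort(want))


def test_qq_points_within_beta_order_statistic_bands():
    """Uniform p-values should sit inside the 95% pointwise beta bands at
    nearly all positions."""
    rng = np.random.default_rng(7)
    from albumin_mr.genetic_association import AssociationResult

    n = 2000
    res = [
        AssociationResult(snp_id=str(i), min_p=p) for i, p in enumerate(rng.random(n))
    ]
    qq, _ = qq_manhattan_tables(res)
    obs = np.sort(10 ** (-qq["observed_neglog10_p"].to_numpy()))
    i = np.arange(1, n + 1)
    lo = stats.beta.ppf(0.025, i, n - i + 1)
    hi = stats.beta.ppf(0.975, i, n - i + 1)
    frac = np.mean((obs >= lo) & (obs <= hi))
    assert frac >= 0.93


# ---------------------------------------------------------------------------
# I/O

def test_tsv_roundtrip(tmp_path, small_cohort):
    gm = small_cohort["genotypes"]
    path = tmp_path / "geno.tsv"
    gm.to_tsv(path)
    back = read_genotypes(path, "tsv-dosage")
    np.testing.assert_array_equal(back.dosage, gm.dosage)
    assert list(back.snp_ids) == list(gm.snp_ids)


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\tD
1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1|1\t./.
1\t200\trs2\tT\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\t1/1
1\t300\trs3\tA\tC,G\t.\tPASS\t.\tGT\t0/0\t0/1\t0/2\t1/1
"""


def test_vcf_reading_minor_allele_orientation(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TEXT)
    with pytest.warns(UserWarning, match="multi-allelic"):
        gm = read_genotypes(path, "vcf")
    assert list(gm.snp_ids) == ["rs1", "rs2"]
    # rs1: ALT freq 3/6 -> stays ALT-counted; het -> 1 regardless of phase
    np.testing.assert_array_equal(gm.column("rs1")[:3], [0, 1, 2])
    assert np.isnan(gm.column("rs1")[3])
    # rs2: ALT freq 7/8 > 0.5 -> dosages count the REF (minor) allele
    np.testing.assert_array_equal(gm.column("rs2"), [0, 0, 1, 0])
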