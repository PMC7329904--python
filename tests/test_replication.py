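"""Ultrasound QC, eBMD derivation, kinship, Z-scores and association."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm_api

from pleioscan.replication import (
    AssociationResult,
    BiobankCohort,
    KINSHIP_CUTOFF,
    KinshipPair,
    MonomorphicError,
    N_PCS,
    QCThresholds,
    apply_qc,
    classify_degree,
    derive_ebmd,
    direction_concordance,
    estimate_kinship,
    kinship_scan,
    select_unrelated,
    snp_association,
    zscore_phenotype,
)
from pleioscan.simulate import simulate_related_pair


class TestDeriveEbmd:
    def test_printed_example(self):
        assert derive_ebmd(1550.0, 80.0) == pytest.approx(0.002592 * 1630 - 3.687)
        assert derive_ebmd(1550.0, 80.0) == pytest.approx(0.53796)

    def test_zero_crossing(self):
        total = 3.687 / 0.002592
        assert derive_ebmd(total, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_slope(self):
        for s, b in [(1500.0, 70.0), (1600.0, 100.0)]:
            assert derive_ebmd(s + 1, b) - derive_ebmd(s, b) == pytest.approx(0.002592)
            assert derive_ebmd(s, b + 1) - derive_ebmd(s, b) == pytest.approx(0.002592)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            derive_ebmd(np.nan, 80.0)
        with pytest.raises(ValueError):
            derive_ebmd(1550.0, np.inf)

    def test_vectorized(self):
        out = derive_ebmd([1550.0, 1600.0], [80.0, 80.0])
        assert out.shape == (2,)


def _cohort(rows):
    cov = pd.DataFrame(rows)
    for j in range(1, N_PCS + 1):
        cov[f"pc{j}"] = 0.0
    cov["entry_mode"] = "direct"
    n = len(cov)
    return BiobankCohort(cov, np.zeros((n, 1), dtype=np.int8), ["rs1"])


def _record(sample_id="S0", sex="male", sos=1550.0, bua=80.0, bmd=0.5, age=55.0, weight=78.0):
    return dict(sample_id=sample_id, sex=sex, age=age, weight=weight,
                sos=sos, bua=bua, bmd_device=bmd)


class TestApplyQC:
    BOUNDS = {
        ("male", "sos"): (1450.0, 1750.0), ("female", "sos"): (1455.0, 1700.0),
        ("male", "bua"): (27.0, 138.0), ("female", "bua"): (22.0, 138.0),
        ("male", "bmd"): (0.18, 1.06), ("female", "bmd"): (0.12, 1.025),
    }

    @pytest.mark.parametrize("sex,measure", list(BOUNDS))
    @pytest.mark.parametrize("side", ["lower", "upper"])
    def test_boundary_value_is_excluded(self, sex, measure, side):
        lo, hi = self.BOUNDS[(sex, measure)]
        value = lo if side == "lower" else hi
        rec = _record(sex=sex)
        rec[{"sos": "sos", "bua": "bua", "bmd": "bmd_device"}[measure]] = value
        retained, report = apply_qc(_cohort([rec]))
        assert retained.n_samples == 0
        row = report[(report["sex"] == sex) & (report["measure"] == measure)]
        assert int(row["n_excluded"].iloc[0]) == 1

    def test_strictly_inside_retained(self):
        rec = _record(sex="female", sos=1500.0, bua=70.0, bmd=0.5)
        retained, _ = apply_qc(_cohort([rec]))
        assert retained.n_samples == 1

    def test_unknown_sex_rejected(self):
        rec = _record(sex="other")
        with pytest.raises(ValueError, match="sex"):
            apply_qc(_cohort([rec]))

    def test_use_ebmd_applies_bound_to_derived_value(self):
        # device value inside bounds, but SOS+BUA imply eBMD below 0.18
        rec = _record(sex="male", sos=1455.0, bua=30.0, bmd=0.5)
        assert derive_ebmd(1455.0, 30.0) < 0.18
        retained_dev, _ = apply_qc(_cohort([rec]))
        retained_ebmd, _ = apply_qc(_cohort([rec]), use_ebmd=True)
        assert retained_dev.n_samples == 1
        assert retained_ebmd.n_samples == 0

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            QCThresholds(sos={"male": (1750.0, 1450.0), "female": (1455.0, 1700.0)})

    def test_synthetic_truth_recovery(self, small_cohort):
        cohort, truth = small_cohort
        retained, _ = apply_qc(cohort)
        kept_ids = set(retained.covariates["sample_id"])
        expect_kept = set(truth.biobank.loc[~truth.biobank["expected_excluded"], "sample_id"])
        assert kept_ids == expect_kept


class TestEstimateKinship:
    @pytest.mark.parametrize("relationship,lo,hi", [
        ("duplicate", 0.45, 0.55),
        ("parent_offspring", 2 ** -2.5, 2 ** -1.5),
        ("full_sib", 2 ** -2.5, 2 ** -1.5),
        ("second_degree", 2 ** -3.5, 2 ** -2.5),
        ("third_degree", 2 ** -4.5, 2 ** -3.5),
    ])
    def test_pedigree_oracle_intervals(self, relationship, lo, hi):
        rng = np.random.default_rng(sum(map(ord, relationship)))
        a, b = simulate_related_pair(relationship, 5000, rng)
        phi = estimate_kinship(a, b)
        assert lo - 0.03 < phi < hi + 0.05

    def test_unrelated_below_cutoff(self):
        rng = np.random.default_rng(12)
        a, b = simulate_related_pair("unrelated", 5000, rng)
        assert abs(estimate_kinship(a, b)) < KINSHIP_CUTOFF

    def test_symmetry_and_allele_flip_invariance(self):
        rng = np.random.default_rng(5)
        a, b = simulate_related_pair("full_sib", 2000, rng)
        phi = estimate_kinship(a, b)
        assert estimate_kinship(b, a) == pytest.approx(phi)
        flip = rng.random(2000) < 0.5
        a2 = np.where(flip, 2 - a, a)
        b2 = np.where(flip, 2 - b, b)
        assert estimate_kinship(a2, b2) == pytest.approx(phi)

    def test_too_few_shared_variants_unassessable(self):
        a = np.array([0, 1, 2] * 10)
        b = np.array([0, 1, 2] * 10)
        assert np.isnan(estimate_kinship(a, b, min_shared=100))

    def test_missing_dosages_skipped(self):
        rng = np.random.default_rng(3)
        a, b = simulate_related_pair("duplicate", 3000, rng)
        a = a.astype(float)
        a[:100] = np.nan
        phi = estimate_kinship(a, b)
        assert 0.45 < phi < 0.55

    def test_classify_degree_intervals(self):
        assert classify_degree(0.5) == "duplicate"
        assert classify_degree(0.25) == "first"
        assert classify_degree(0.125) == "second"
        assert classify_degree(0.0625) == "third"
        assert classify_degree(0.01) == "unrelated"


class TestKinshipScan:
    def test_scan_matches_per_pair_estimator(self):
        rng = np.random.default_rng(8)
        maf = rng.uniform(0.1, 0.5, 800)
        g = ((rng.random((12, 800)) < maf).astype(np.int8)
             + (rng.random((12, 800)) < maf).astype(np.int8))
        g[1] = g[0]  # plant one duplicate
        ids = [f"S{i}" for i in range(12)]
        pairs = kinship_scan(g, ids, cutoff=-1.0, chunk=5)
        got = {(p.sample_a, p.sample_b): p.phi for p in pairs}
        for i in range(12):
            for j in range(i + 1, 12):
                want = estimate_kinship(g[i], g[j])
                assert got[(ids[i], ids[j])] == pytest.approx(want, abs=1e-6)

    def test_scan_finds_planted_close_relatives(self, small_cohort):
        cohort, truth = small_cohort
        pairs = kinship_scan(cohort.dosages, cohort.covariates["sample_id"])
        found = {frozenset((p.sample_a, p.sample_b)) for p in pairs}
        close = truth.pairs[truth.pairs["expected_phi"] >= 0.25]
        planted = {
            frozenset((a, b))
            for a, b in zip(close["sample_a"], close["sample_b"])
        }
        # duplicates and first-degree pairs sit far above the cutoff even
        # at this small marker count and must all be detected
        assert planted and planted <= found


class TestSelectUnrelated:
    def test_one_duplicate_pair_removes_one(self):
        pairs = [KinshipPair("S1", "S2", 0.5)]
        kept = select_unrelated(["S1", "S2", "S3"], pairs)
        assert kept == ["S1", "S3"]  # lexicographically larger member removed

    def test_no_pairs_all_retained(self):
        kept = select_unrelated(["S1", "S2"], [])
        assert kept == ["S1", "S2"]

    def test_triangle_retains_exactly_one(self):
        pairs = [KinshipPair("S1", "S2", 0.3), KinshipPair("S2", "S3", 0.3),
                 KinshipPair("S1", "S3", 0.3)]
        kept = select_unrelated(["S1", "S2", "S3"], pairs)
        assert kept == ["S1"]

    def test_below_threshold_pairs_ignored(self):
        pairs = [KinshipPair("S1", "S2", 0.01)]
        assert select_unrelated(["S1", "S2"], pairs) == ["S1", "S2"]

    def test_no_residual_related_pair(self):
        rng = np.random.default_rng(4)
        ids = [f"S{i}" for i in range(30)]
        pairs = [
            KinshipPair(ids[i], ids[j], 0.3)
            for i in range(30) for j in range(i + 1, 30) if rng.random() < 0.1
        ]
        kept = set(select_unrelated(ids, pairs))
        for p in pairs:
            assert not (p.sample_a in kept and p.sample_b in kept)


def _zs_frame(n, rng, sex=None):
    cov = pd.DataFrame(dict(
        sample_id=[f"S{i}" for i in range(n)],
        sex=sex if sex is not None else rng.choice(["male", "female"], n),
        age=rng.uniform(40, 69, n),
        weight=rng.normal(78, 10, n),
    ))
    cov["bmd_device"] = (0.5 - 0.002 * cov["age"] + 0.001 * cov["weight"]
                         + rng.normal(0, 0.08, n))
    return cov


class TestZscorePhenotype:
    def test_mean_zero_sd_one_per_sex(self):
        rng = np.random.default_rng(10)
        cov = _zs_frame(400, rng)
        z, _ = zscore_phenotype(cov, z_bound=np.inf)
        for sex in ("male", "female"):
            ids = cov.loc[cov["sex"] == sex, "sample_id"]
            assert z[ids].mean() == pytest.approx(0.0, abs=1e-10)
            assert z[ids].std(ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_outlier_beyond_four_excluded(self):
        rng = np.random.default_rng(11)
        cov = _zs_frame(300, rng, sex=["male"] * 300)
        cov.loc[0, "bmd_device"] += 1.0  # ~ 12 residual SDs
        z, excluded = zscore_phenotype(cov)
        assert "S0" in excluded
        assert "S0" not in z.index

    def test_matches_normal_equations_oracle_on_six_samples(self):
        cov = pd.DataFrame(dict(
            sample_id=[f"S{i}" for i in range(6)],
            sex=["female"] * 6,
            age=[41.0, 45.0, 50.0, 55.0, 60.0, 65.0],
            weight=[60.0, 70.0, 80.0, 75.0, 68.0, 90.0],
            bmd_device=[0.50, 0.52, 0.47, 0.55, 0.44, 0.58],
        ))
        z, _ = zscore_phenotype(cov, z_bound=np.inf)
        X = np.column_stack([
            np.ones(6), cov["age"], cov["age"] ** 2, cov["weight"]])
        y = cov["bmd_device"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        expect = resid / resid.std(ddof=1)
        np.testing.assert_allclose(z[cov["sample_id"]].to_numpy(), expect, atol=1e-8)

    def test_too_few_samples_in_stratum_rejected(self):
        rng = np.random.default_rng(1)
        cov = _zs_frame(3, rng, sex=["male"] * 3)
        with pytest.raises(ValueError, match="too few"):
            zscore_phenotype(cov)


class TestSnpAssociation:
    def test_orthogonal_dosage_gives_zero_beta(self):
        rng = np.random.default_rng(20)
        n = 60
        z = rng.standard_normal(n)
        pcs = rng.standard_normal((n, N_PCS))
        raw = rng.integers(0, 3, n).astype(float)
        basis, _ = np.linalg.qr(np.column_stack([np.ones(n), z, pcs]))
        g = raw - basis @ (basis.T @ raw)  # orthogonal to 1, z and all PCs
        g = g - g.min()  # keep dosages non-negative; shift is absorbed by the intercept
        res = snp_association(z, g, pcs)
        assert res.beta == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_planted_slope_recovered_exactly(self):
        rng = np.random.default_rng(21)
        n = 30
        g = rng.integers(0, 3, n).astype(float)
        pcs = rng.standard_normal((n, N_PCS))
        z = 0.5 * g  # no noise, no PC signal
        res = snp_association(z, g, pcs)
        assert res.beta == pytest.approx(0.5, abs=1e-10)

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            n = 50
            g = rng.integers(0, 3, n).astype(float)
            pcs = rng.standard_normal((n, N_PCS))
            z = 0.1 * g + pcs @ rng.normal(0, 0.05, N_PCS) + rng.standard_normal(n)
            res = snp_association(z, g, pcs)
            X = sm_api.add_constant(np.column_stack([g, pcs]))
            fit = sm_api.OLS(z, X).fit()
            assert res.beta == pytest.approx(fit.params[1], rel=1e-8)
            assert res.se == pytest.approx(fit.bse[1], rel=1e-8)
            assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_mean_imputation_of_missing_dosage(self):
        rng = np.random.default_rng(23)
        n = 40
        g = rng.integers(0, 3, n).astype(float)
        g[0] = -1  # missing
        pcs = rng.standard_normal((n, N_PCS))
        z = rng.standard_normal(n)
        res = snp_association(z, g, pcs)
        assert res.n_used == n
        res_drop = snp_association(z, g, pcs, missing="drop")
        assert res_drop.n_used == n - 1

    def test_monomorphic_rejected(self):
        n = 40
        z = np.random.default_rng(0).standard_normal(n)
        with pytest.raises(MonomorphicError):
            snp_association(z, np.ones(n), np.zeros((n, N_PCS)))

    def test_ci_and_replicated_flag(self):
        res = AssociationResult("rs1", "G", "A", 0.3, 0.1, 0.01, 1e-9, 100)
        lo, hi = res.ci95
        assert lo == pytest.approx(0.1 - 1.96 * 0.01)
        assert hi == pytest.approx(0.1 + 1.96 * 0.01)
        assert res.replicated
        assert not AssociationResult("rs1", "G", "A", 0.3, 0.1, 0.01, 1e-7, 100).replicated


def _disc(rsid="rs1", ea="G", oa="A", beta=0.02, eaf=0.3):
    return pd.DataFrame([dict(rsid=rsid, chrom="1", pos=1000, ea=ea, oa=oa,
                              eaf=eaf, beta=beta, se=0.01, p=1e-9, n=50_000)])


def _assoc(rsid="rs1", ea="G", oa="A", beta=0.01):
    return AssociationResult(rsid, ea, oa, 0.3, beta, 0.001, 1e-10, 1000)


class TestDirectionConcordance:
    def test_same_allele_same_sign_concordant(self):
        table, frac = direction_concordance(_disc(beta=0.02), [_assoc(beta=0.01)])
        assert table["concordant"].iloc[0]
        assert frac == 1.0

    def test_swapped_alleles_flip_sign(self):
        table, frac = direction_concordance(
            _disc(ea="G", oa="A", beta=0.02), [_assoc(ea="A", oa="G", beta=-0.02)])
        assert table["concordant"].iloc[0]
        assert frac == 1.0

    def test_palindromic_high_maf_ambiguous(self):
        table, frac = direction_concordance(
            _disc(ea="A", oa="T", eaf=0.49), [_assoc(ea="A", oa="T")])
        assert table["status"].iloc[0] == "ambiguous_palindromic"
        assert np.isnan(frac)

    def test_palindromic_low_maf_compared(self):
        table, _ = direction_concordance(
            _disc(ea="A", oa="T", eaf=0.1), [_assoc(ea="A", oa="T")])
        assert table["status"].iloc[0] == "compared"

    def test_allele_mismatch_excluded_from_denominator(self):
        table, frac = direction_concordance(
            _disc(ea="G", oa="A"), [_assoc(ea="C", oa="A"), _assoc("rs1", "G", "A", -0.5)])
        assert "allele_mismatch" in set(table["status"])
        assert frac == 0.0  # only the discordant comparable SNP counts

    def test_empty_replication_list(self):
        table, frac = direction_concordance(_disc(), [])
        assert len(table) == 0 and "status" in table.columns
        assert np.isnan(frac)

    def test_overall_fraction(self):
        disc = pd.concat([_disc("rs1", beta=0.02), _disc("rs2", beta=0.02),
                          _disc("rs3", beta=0.02)])
        reps = [_assoc("rs1", beta=0.01), _assoc("rs2", beta=0.01),
                _assoc("rs3", beta=-0.01)]
        _, frac = direction_concordance(disc, reps)
        assert frac == pytest.approx(2 / 3)
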