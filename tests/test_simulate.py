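"""The synthetic duo-cohort generator."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import bwburden as b
from bwburden.cohort import MISSING


def _minimal_config(**kw):
    defaults = dict(
        n_duos=200,
        gene_specs=(b.GeneSpec("G", (b.VariantSpec(af=0.01),)),),
        covariate_effects={},
        reporting=b.ReportingConfig(n_visits=1),
        seed=1,
    )
    defaults.update(kw)
    return b.SimulationConfig(**defaults)


class TestConfigValidation:
    def test_bad_allele_frequency(self):
        with pytest.raises(ValueError):
            b.VariantSpec(af=0.0)
        with pytest.raises(ValueError):
            b.VariantSpec(af=1.0)

    def test_nonfinite_effect(self):
        with pytest.raises(ValueError):
            b.GeneSpec("G", (b.VariantSpec(af=0.1),), beta_fetal=float("inf"))

    def test_rates_bounded(self):
        with pytest.raises(ValueError):
            b.ArtifactRates(missing_rate=1.5)
        with pytest.raises(ValueError):
            b.ReportingConfig(discordant_rate=-0.1)

    def test_n_duos_positive(self):
        with pytest.raises(ValueError):
            _minimal_config(n_duos=0)


class TestGenotypeStructure:
    def test_mother_child_dosage_correlation(self):
        """Transmission of one maternal allele plus a population draw gives
        r = 0.5 between maternal and fetal dosages at any frequency."""
        cfg = _minimal_config(
            n_duos=60_000,
            gene_specs=(b.GeneSpec("G", (b.VariantSpec(af=0.3),)),),
        )
        cohort = b.simulate_duos(cfg)
        n = cfg.n_duos
        child = cohort.genotypes.gt[0, :n].astype(float)
        mother = cohort.genotypes.gt[0, n:].astype(float)
        assert pearsonr(child, mother).statistic == pytest.approx(0.5, abs=0.02)

    def test_mendelian_consistency(self):
        """A child's alt alleles are explained by the maternal genotype
        plus the recorded paternal population draw."""
        cfg = _minimal_config(
            n_duos=5000,
            gene_specs=(b.GeneSpec("G", (b.VariantSpec(af=0.05), b.VariantSpec(af=0.2))),),
        )
        cohort = b.simulate_duos(cfg)
        n = cfg.n_duos
        child = cohort.genotypes.gt[:, :n].astype(int)
        mother = cohort.genotypes.gt[:, n:].astype(int)
        paternal = cohort.truth["paternal"].astype(int)
        max_transmitted = np.minimum(mother, 1)
        assert (child <= max_transmitted + paternal).all()
        assert (child >= paternal + (mother == 2)).all()

    def test_mothers_female_and_linked(self):
        cohort = b.simulate_duos(_minimal_config())
        assert (cohort.persons.loc[cohort.mothers, "sex"] == "F").all()
        assert set(cohort.mother_of().values()) == set(cohort.mothers)


class TestPhenotypeModel:
    def test_null_architecture(self):
        """Zero gene specs: the phenotype is covariates plus noise only and
        no genotypes exist to collapse."""
        cfg = b.SimulationConfig(n_duos=100, gene_specs=(), seed=2)
        cohort = b.simulate_duos(cfg)
        assert cohort.genotypes.n_variants == 0
        assert len(cohort.truth["carriers"]) == 0

    def test_latent_sd_matches_noise_only_model(self):
        cfg = b.SimulationConfig(
            n_duos=4000, gene_specs=(), covariate_effects={}, noise_sd=1.0, seed=3
        )
        cohort = b.simulate_duos(cfg)
        sd = cohort.truth["latent"].std(ddof=1)
        assert sd == pytest.approx(1.0, abs=3 / np.sqrt(cfg.n_duos))

    def test_kg_mapping(self):
        cfg = _minimal_config(bw_mean_kg=3.2, bw_sd_kg=0.4)
        cohort = b.simulate_duos(cfg)
        np.testing.assert_allclose(
            cohort.truth["true_bw_kg"], 3.2 + 0.4 * cohort.truth["latent"]
        )

    def test_marginal_recovery_of_planted_gene(self):
        """With a common variant for precision, marginal regressions see
        beta_F + 0.5 beta_M (fetal) and beta_M + 0.5 beta_F (maternal)."""
        gene = b.GeneSpec(
            "G", tuple(b.VariantSpec(af=5e-4) for _ in range(20)),
            beta_fetal=-0.311, beta_maternal=0.430,
        )
        cfg = _minimal_config(n_duos=60_000, gene_specs=(gene,), noise_sd=1.0)
        cohort = b.simulate_duos(cfg)
        truth = cohort.truth["carriers"]["G"]
        y = b.standardize(cohort.truth["latent"].to_numpy())
        sl = lambda x: np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        bf = sl(truth["child_carrier"].to_numpy(dtype=float))
        bm = sl(truth["mother_carrier"].to_numpy(dtype=float))
        n_c = truth["child_carrier"].sum()
        mc = 3.0 / np.sqrt(n_c)
        assert bf == pytest.approx(-0.311 + 0.5 * 0.430, abs=mc)
        assert bm == pytest.approx(0.430 + 0.5 * -0.311, abs=mc)


class TestReads:
    def test_zero_artifacts_clean(self):
        cfg = _minimal_config(artifact_rates=b.ArtifactRates(0, 0, 0, 0))
        cohort = b.simulate_reads(b.simulate_duos(cfg))
        gm = cohort.genotypes
        assert (gm.gt != MISSING).all()
        het = gm.gt == 1
        np.testing.assert_array_equal((gm.ad_ref + gm.ad_alt)[het], gm.dp[het])
        assert (gm.dp[het] >= 1).all()

    def test_biased_variant_mean_allele_fraction(self):
        """With bias_p = 0.2 the mean het alt fraction sits near 0.2."""
        gene = b.GeneSpec("G", (b.VariantSpec(af=0.3, allele_biased=True),))
        cfg = _minimal_config(
            n_duos=3000, gene_specs=(gene,),
            artifact_rates=b.ArtifactRates(0, 0, 0, 0), bias_p=0.2,
        )
        cohort = b.simulate_reads(b.simulate_duos(cfg))
        gm = cohort.genotypes
        het = gm.gt[0] == 1
        frac = gm.ad_alt[0, het] / gm.dp[0, het]
        assert frac.mean() == pytest.approx(0.2, abs=0.02)

    def test_full_missingness(self):
        cfg = _minimal_config(artifact_rates=b.ArtifactRates(0, 0, 0, 1.0))
        cohort = b.simulate_reads(b.simulate_duos(cfg))
        assert (cohort.genotypes.gt == MISSING).all()
        from bwburden.qc import apply_variant_filters

        _, counts = apply_variant_filters(cohort.genotypes)
        assert counts["missingness"] == cohort.genotypes.n_variants

    def test_input_cohort_untouched(self):
        clean = b.simulate_duos(_minimal_config())
        before = clean.genotypes.gt.copy()
        b.simulate_reads(clean, b.ArtifactRates(0.5, 0.5, 0.5, 0.5))
        np.testing.assert_array_equal(clean.genotypes.gt, before)


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        cfg = b.default_config(n_duos=120, seed=42)
        a = b.emit_cohort(b.simulate_cohort(cfg), tmp_path / "a")
        bb = b.emit_cohort(b.simulate_cohort(cfg), tmp_path / "b")
        for name in a:
            assert open(a[name], "rb").read() == open(bb[name], "rb").read()

    def test_different_seed_differs(self, tmp_path):
        a = b.emit_cohort(b.simulate_cohort(b.default_config(50, seed=1)), tmp_path / "a")
        bb = b.emit_cohort(b.simulate_cohort(b.default_config(50, seed=2)), tmp_path / "b")
        assert open(a["vcf"], "rb").read() != open(bb["vcf"], "rb").read()


class TestReporting:
    def test_hospital_rate_one(self):
        cfg = _minimal_config(
            reporting=b.ReportingConfig(n_visits=1, hospital_record_rate=1.0,
                                        discordant_rate=0, extreme_rate=0)
        )
        cohort = b.simulate_duos(cfg)
        per_mother = cohort.offspring_reports.groupby("mother_id")["source"].agg(set)
        assert all("hospital" in s for s in per_mother)

    def test_discordant_rate_injects_spread(self):
        cfg = _minimal_config(
            n_duos=500,
            reporting=b.ReportingConfig(n_visits=2, discordant_rate=1.0,
                                        extreme_rate=0, multiple_birth_rate=0),
        )
        cohort = b.simulate_duos(cfg)
        spread = cohort.own_reports.groupby("person_id")["value_kg"].agg(
            lambda v: v.max() - v.min()
        )
        assert (spread > 1.0).all()
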