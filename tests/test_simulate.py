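"""The synthetic-cohort generator and its planted ground truth."""

import math
from collections import Counter
from pathlib import Path

import numpy as np
import pytest

from corepromoter.promoters import read_promoter_table
from corepromoter.simulate import SimConfig, simulate, write_fixture_suite
from corepromoter.spectrum import substitution_spectrum
from corepromoter.variants import (
    read_cohort_vcf,
    read_flag_table,
    run_filters,
    write_retained_table,
)


def small_cfg(**kw):
    base = dict(
        seed=5, n_samples_a=20, n_samples_b=25, n_genes=15,
        n_true_somatic=8, n_true_germline=3, germline_fraction=0.4,
        n_polymorphic_background=4, n_private_background=4,
    )
    base.update(kw)
    return SimConfig(**base)


def retained_keys(variants):
    return {
        (v.key.chrom, v.key.pos, v.key.ref, v.key.alt)
        for v in variants
        if v.status == "retained"
    }


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        p1 = simulate(small_cfg(seed=7)).write(tmp_path / "a")
        p2 = simulate(small_cfg(seed=7)).write(tmp_path / "b")
        for name in p1:
            assert Path(p1[name]).read_bytes() == Path(p2[name]).read_bytes(), name

    def test_different_seed_differs(self, tmp_path):
        p1 = simulate(small_cfg(seed=7)).write(tmp_path / "a")
        p2 = simulate(small_cfg(seed=8)).write(tmp_path / "b")
        assert Path(p1["vcf_a"]).read_bytes() != Path(p2["vcf_a"]).read_bytes()


class TestGroundTruthRecovery:
    def test_pipeline_recovers_planted_set_in_memory(self, small_sim):
        cfg = small_sim.config
        filtered = run_filters(
            small_sim.to_cohort_variants("a"), cfg.n_samples_a,
            cfg.somatic_fraction, cfg.germline_fraction,
        )
        assert retained_keys(filtered) == small_sim.expected_retained("a")
        statuses = Counter(v.status for v in filtered)
        expected = Counter(v.expected_status for v in small_sim.cohorts["a"])
        assert statuses == expected

    def test_pipeline_recovers_planted_set_from_files(self, small_sim, small_sim_dir):
        cfg = small_sim.config
        pset = read_promoter_table(small_sim_dir["promoters"])
        for cohort, n in (("a", cfg.n_samples_a), ("b", cfg.n_samples_b)):
            flags = read_flag_table(small_sim_dir[f"flags_{cohort}"])
            called = read_cohort_vcf(small_sim_dir[f"vcf_{cohort}"], pset, flags)
            filtered = run_filters(called, n, cfg.somatic_fraction, cfg.germline_fraction)
            assert retained_keys(filtered) == small_sim.expected_retained(cohort)

    def test_planted_flags_consistent_with_class(self, small_sim):
        for v in small_sim.cohorts["a"]:
            if v.expected_status != "retained":
                continue
            has_db = any(v.db_flags.values())
            assert has_db == (v.true_class == "germline")
            assert not v.panel_flag
            assert 2 <= len(v.carriers)


class TestConfigValidation:
    def test_infeasible_germline_threshold(self):
        # at 5% of 20 samples the threshold is 1: recurrent germline
        # mutations cannot survive, so planting them must fail loudly
        with pytest.raises(ValueError, match="infeasible"):
            simulate(small_cfg(germline_fraction=0.05))

    def test_too_many_variants_for_windows(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate(small_cfg(n_genes=1, n_true_somatic=500))

    def test_bad_probability(self):
        with pytest.raises(ValueError):
            simulate(small_cfg(transition_prob=1.5))


class TestSpectrumRecovery:
    def test_doubled_tstv_converges_to_planted_rate(self):
        """2xTs/Tv from planted substitutions approaches 2p/(1-p)."""
        p = 0.5
        cfg = SimConfig(
            seed=13, n_samples_a=10, n_samples_b=10, n_genes=8,
            n_true_somatic=500, n_true_germline=0,
            somatic_type_probs=(1.0, 0.0, 0.0), transition_prob=p,
            n_polymorphic_background=0, n_private_background=0,
        )
        sim = simulate(cfg)
        spec = substitution_spectrum(v.key for v in sim.cohorts["a"])
        n = spec.ts_total + spec.tv_total
        assert n == 500
        se = math.sqrt(p * (1 - p) / n)
        assert abs(spec.ts_total / n - p) <= 3 * se
        assert spec.ts_tv_ratio == pytest.approx(2 * p / (1 - p), rel=0.2)


class TestMotifEnrichment:
    def test_hit_fraction_monotone_in_enrichment(self):
        """Planted mutations land in motif windows more often as the
        enrichment factor grows (averaged over replicates)."""
        from corepromoter.motifs import annotate_motifs, default_catalogue

        cat = default_catalogue()
        fractions = []
        for enrich in (1.0, 3.0, 9.0):
            frac = []
            for rep in range(10):
                sim = simulate(
                    small_cfg(seed=100 + rep, motif_enrichment=enrich,
                              n_true_somatic=20, n_polymorphic_background=0,
                              n_private_background=0)
                )
                muts = sim.to_cohort_variants("a")
                hits, _ = annotate_motifs(muts, cat)
                hit_keys = {(h.variant_key, h.gene_id) for h in hits}
                frac.append(len(hit_keys) / len(muts))
            fractions.append(np.mean(frac))
        assert fractions[0] < fractions[1] < fractions[2]


class TestDeCoupling:
    def test_strong_coupling_yields_association(self):
        """de_coupling far above the background alteration rate produces an
        odds ratio > 1 with Fisher p < 0.05 at a few hundred genes."""
        from corepromoter.expression import link_mutations_to_de

        cfg = SimConfig(
            seed=21, n_samples_a=30, n_samples_b=30, n_genes=300,
            n_true_somatic=60, n_true_germline=0, de_coupling=0.8,
            de_background_rate=0.05,
            n_polymorphic_background=0, n_private_background=0,
        )
        sim = simulate(cfg)
        mutated = {v.gene_id for v in sim.cohorts["a"] if v.expected_status == "retained"}
        link = link_mutations_to_de(mutated, sim.de_table)
        assert link.odds_ratio > 1
        assert link.fisher_p < 0.05


class TestSharedFraction:
    def test_zero_sharing_gives_disjoint_cohorts(self):
        sim = simulate(small_cfg(shared_fraction=0.0))
        a = {v.key for v in sim.cohorts["a"]}
        b = {v.key for v in sim.cohorts["b"]}
        assert not a & b

    def test_full_sharing_keeps_all_retained(self):
        sim = simulate(small_cfg(shared_fraction=1.0))
        a = {v.key for v in sim.cohorts["a"] if v.expected_status == "retained"}
        b = {v.key for v in sim.cohorts["b"] if v.expected_status == "retained"}
        assert a <= b


class TestFixtureSuite:
    def test_every_filter_status_present(self, fixture_dir):
        pset = read_promoter_table(fixture_dir["promoters"])
        flags = read_flag_table(fixture_dir["flags"])
        called = read_cohort_vcf(fixture_dir["vcf"], pset, flags)
        filtered = run_filters(called, 5, 0.5, 0.5)
        assert {v.status for v in filtered} == {
            "retained", "eliminated_panel",
            "eliminated_polymorphic", "eliminated_private",
        }

    def test_matches_committed_expected_output(self, fixture_dir, tmp_path):
        import pandas as pd

        pset = read_promoter_table(fixture_dir["promoters"])
        flags = read_flag_table(fixture_dir["flags"])
        called = read_cohort_vcf(fixture_dir["vcf"], pset, flags)
        filtered = run_filters(called, 5, 0.5, 0.5)
        out = tmp_path / "retained.tsv"
        write_retained_table(filtered, out)
        got = pd.read_csv(out, sep="\t")
        expected = pd.read_csv(fixture_dir["expected_retained"], sep="\t")
        pd.testing.assert_frame_equal(got, expected)
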