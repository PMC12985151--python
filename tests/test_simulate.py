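"""Synthetic-data generator: determinism, Hardy-Weinberg structure,
Mendelian pedigrees, founder effects, and artifact injection."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ssrkit.model import NULL_ALLELE
from ssrkit.popgen import (allele_frequencies, marker_stats, null_allele_estimate,
                           observed_heterozygosity, panel_summary, pic,
                           probability_identity)
from ssrkit.parentage import trio_mismatch
from ssrkit.simulate import (SimConfig, inject_artifacts, max_pic, simulate_cross,
                             simulate_founder_population, simulate_frequencies,
                             simulate_panel_frequencies, simulate_population)


class TestSimulateFrequencies:
    def test_single_allele_degenerate(self):
        fr = simulate_frequencies(1, seed=0)
        assert fr.freqs == {100: 1.0}
        assert pic(fr) == 0.0

    def test_seeded_determinism(self):
        a = simulate_frequencies(5, seed=42)
        b = simulate_frequencies(5, seed=42)
        assert a == b
        assert a != simulate_frequencies(5, seed=43)

    def test_target_pic_two_alleles_near_equifrequent(self):
        # PIC 0.375 is the 2-allele maximum, attained only near p = 0.5
        fr = simulate_frequencies(2, target_pic=0.375, seed=1, tol=0.02)
        p = sorted(fr.freqs.values())
        assert abs(p[0] - 0.5) < 0.15
        assert pic(fr) == pytest.approx(0.375, abs=0.02)

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            simulate_frequencies(2, target_pic=0.8, seed=0)

    def test_lattice_lengths(self):
        fr = simulate_frequencies(4, seed=3, motif_len=3, base_len=200)
        assert list(fr.freqs) == [200, 203, 206, 209]


class TestSimulatePopulation:
    def test_ho_within_binomial_error(self):
        fr = simulate_frequencies(2, target_pic=0.375, seed=10, tol=0.001)
        pop = simulate_population({"M": fr}, 10_000, seed=11)
        p = list(fr.freqs.values())
        he = 1 - sum(x * x for x in p)
        se = math.sqrt(he * (1 - he) / 10_000)
        assert abs(observed_heterozygosity(pop, "M") - he) < 3 * se

    def test_frequency_recovery_improves_with_n(self):
        fr = simulate_frequencies(6, seed=20)
        errs = []
        for n in (100, 1000, 10_000):
            pop = simulate_population({"M": fr}, n, seed=21)
            est = allele_frequencies(pop, "M").freqs
            errs.append(max(abs(est.get(a, 0.0) - p) for a, p in fr.freqs.items()))
        assert errs[2] < errs[0]
        assert errs[2] < 0.02

    def test_empirical_match_probability_validates_pi(self):
        # end-to-end: empirical genotype-match frequency ~ per-locus PI
        fr = simulate_frequencies(4, seed=30, concentration=3.0)
        pop = simulate_population({"M": fr}, 4000, seed=31)
        calls = [pop.row(i)["M"] for i in range(len(pop))]
        half = len(calls) // 2
        matches = sum(a == b for a, b in zip(calls[:half], calls[half:]))
        emp = matches / half
        expected = probability_identity(fr)
        se = math.sqrt(expected * (1 - expected) / half)
        assert abs(emp - expected) < 4 * se

    def test_panel_pi_total_multiplies_over_independent_loci(self):
        cfg = SimConfig(n_markers=4, seed=32)
        freqs = simulate_panel_frequencies(cfg)
        pop = simulate_population(freqs, 500, seed=33)
        ps = panel_summary(pop)
        assert ps.pi_total == pytest.approx(
            math.prod(s.pi for s in ps.per_marker))


class TestSimulateCross:
    def test_homozygous_parents_fixed_offspring(self):
        from ssrkit.model import GenotypeCall

        p = {"M": GenotypeCall.of(100, 100)}
        q = {"M": GenotypeCall.of(104, 104)}
        kids = simulate_cross(p, q, 20, seed=1)
        assert all(k["M"].alleles == (100, 104) for k in kids)

    def test_zero_mutation_rate_always_trio_compatible(self):
        cfg = SimConfig(n_markers=10, seed=40)
        freqs = simulate_panel_frequencies(cfg)
        pop = simulate_population(freqs, 2, seed=41)
        for k in simulate_cross(pop.row(0), pop.row(1), 50, seed=42):
            assert trio_mismatch(k, pop.row(0), pop.row(1)) == 0

    def test_selfing_mendelian_ratio(self):
        from ssrkit.model import GenotypeCall

        p = {"M": GenotypeCall.of(100, 102)}
        kids = simulate_cross(p, p, 4000, seed=43)
        counts = {g: 0 for g in ["AA", "AB", "BB"]}
        for k in kids:
            a, b = k["M"].alleles
            counts["AA" if (a, b) == (100, 100) else
                   "BB" if (a, b) == (102, 102) else "AB"] += 1
        # 1:2:1 within 4 binomial s.e.
        for key, expect in (("AA", 0.25), ("AB", 0.5), ("BB", 0.25)):
            se = math.sqrt(expect * (1 - expect) / 4000)
            assert abs(counts[key] / 4000 - expect) < 4 * se

    def test_mutation_rate_produces_mismatches(self):
        cfg = SimConfig(n_markers=10, seed=44)
        freqs = simulate_panel_frequencies(cfg)
        pop = simulate_population(freqs, 2, seed=45)
        kids = simulate_cross(pop.row(0), pop.row(1), 50, seed=46,
                              mutation_rate=0.2)
        assert sum(trio_mismatch(k, pop.row(0), pop.row(1)) for k in kids) > 0


class TestFounderPopulation:
    def test_allele_conservation_two_founders(self):
        cfg = SimConfig(n_markers=6, seed=50)
        freqs = simulate_panel_frequencies(cfg)
        founders = simulate_population(freqs, 2, seed=51)
        table, _ = simulate_founder_population(founders, 4, 20, seed=52)
        for m in table.panel.marker_names:
            assert marker_stats(table, m).k <= 4  # at most 4 founder alleles

    def test_pedigree_trios_all_compatible(self):
        cfg = SimConfig(n_markers=6, seed=53)
        freqs = simulate_panel_frequencies(cfg)
        founders = simulate_population(freqs, 4, seed=54)
        table, pedigree = simulate_founder_population(founders, 3, 15, seed=55)
        assert len(pedigree) == 45
        for rec in pedigree:
            assert trio_mismatch(table.row_by_name(rec.child),
                                 table.row_by_name(rec.parent_a),
                                 table.row_by_name(rec.parent_b)) == 0

    def test_diversity_decays_down_generations(self):
        # founder effect: deep generations lose PIC and Ae vs the base pool
        cfg = SimConfig(n_markers=10, seed=56)
        freqs = simulate_panel_frequencies(cfg)
        founders = simulate_population(freqs, 50, seed=57)
        table, _ = simulate_founder_population(founders, 5, 30, seed=58)
        base = [s for s in table.samples if s.startswith("S")]
        deep = [s for s in table.samples if s.startswith("G5_")]
        stats_base = panel_summary(table.subset(base))
        stats_deep = panel_summary(table.subset(deep))
        assert stats_deep.averages["pic"] <= stats_base.averages["pic"]
        assert stats_deep.averages["ae"] <= stats_base.averages["ae"]
        assert stats_deep.pi_total >= stats_base.pi_total


class TestInjectArtifacts:
    def test_noop_when_rates_zero(self):
        cfg = SimConfig(n_markers=4, seed=60)
        freqs = simulate_panel_frequencies(cfg)
        pop = simulate_population(freqs, 10, seed=61)
        out, log = inject_artifacts(pop, seed=62)
        assert out == pop
        assert not log.null_alleles and not log.clones and not log.typos

    def test_null_injection_masks_heterozygotes(self):
        cfg = SimConfig(n_markers=8, seed=63)
        freqs = simulate_panel_frequencies(cfg)
        pop = simulate_population(freqs, 400, seed=64)
        dirty, log = inject_artifacts(pop, null_allele_rate=0.15, seed=65)
        assert log.null_alleles  # something was masked
        # masked calls appear homozygous or as no-amplification
        for m, events in log.null_alleles.items():
            for label, _orig in events:
                now = dirty.call(label, m)
                assert (not now.is_heterozygous) or now.is_null
        # heterozygote deficit drives the null estimator positive on average
        ests = []
        for m in pop.panel.marker_names:
            s = marker_stats(dirty, m)
            ests.append(null_allele_estimate(s.ho, s.he))
        assert np.mean(ests) > 0

    def test_ho_decreases_under_nulls(self):
        cfg = SimConfig(n_markers=8, seed=66)
        freqs = simulate_panel_frequencies(cfg)
        pop = simulate_population(freqs, 400, seed=67)
        dirty, _ = inject_artifacts(pop, null_allele_rate=0.15, seed=68)
        ho_clean = np.mean([observed_heterozygosity(pop, m)
                            for m in pop.panel.marker_names])
        ho_dirty = np.mean([observed_heterozygosity(dirty, m)
                            for m in pop.panel.marker_names])
        assert ho_dirty < ho_clean

    def test_typos_logged_and_applied(self):
        cfg = SimConfig(n_markers=6, seed=69)
        freqs = simulate_panel_frequencies(cfg)
        pop = simulate_population(freqs, 50, seed=70)
        dirty, log = inject_artifacts(pop, replicate_error_rate=0.1, seed=71)
        assert log.typos
        for label, m, orig, new in log.typos:
            assert dirty.call(label, m) == new and new != orig

    def test_max_pic_is_equifrequent_ceiling(self):
        for k in (2, 3, 4, 6):
            ceiling = max_pic(k)
            rng = np.random.default_rng(k)
            for _ in range(50):
                w = rng.uniform(0.05, 1.0, k)
                p = w / w.sum()
                from ssrkit.popgen import AlleleFrequencies

                fr = AlleleFrequencies("m", {100 + 2 * i: float(x)
                                             for i, x in enumerate(p)}, 2 * k)
                assert pic(fr) <= ceiling + 1e-9
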