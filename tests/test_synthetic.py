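"""Generator correctness: divergence, F2 segregation, coverage, Hi-C decay."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allopolyphase import synthetic as syn
from allopolyphase.genomes import Genome, n_windows


class TestAllotetraploid:
    def test_no_exchange_yields_pure_chromosomes(self):
        pair, tet, truth = syn.simulate_allotetraploid(2, 120_000, 0.01, seed=0)
        assert tet.names == ["O1", "R1", "O2", "R2"]
        assert truth.he_breakpoints == []

    def test_exchange_yields_reciprocal_breakpoints(self, he_system):
        _, tet, truth = he_system
        assert len(tet.names) == 8
        assert {"O2_R2", "R2_O2"} < set(tet.names)
        assert len(truth.he_breakpoints) == 2
        (a, pa), (b, pb) = truth.he_breakpoints
        assert pa == pb  # reciprocal exchange at the same coordinate
        assert {a, b} == {"O2_R2", "R2_O2"}

    def test_hybrid_sequence_switches_source(self, he_system):
        pair, tet, truth = he_system
        bp = truth.breakpoint_of("O2_R2")
        assert tet["O2_R2"][:bp] == pair.genome_o["O2"][:bp]
        assert tet["O2_R2"][bp:] == pair.genome_r["R2"][bp:]

    def test_planted_variant_count_matches_binomial(self):
        length, rate = 1_000_000, 0.01
        pair = syn.make_subgenome_pair(1, length, rate, seed=42)
        n = len(pair.true_variants)
        mean = length * rate
        sigma = np.sqrt(length * rate * (1 - rate))
        assert abs(n - mean) < 3 * sigma

    def test_variants_differ_between_subgenomes(self):
        pair = syn.make_subgenome_pair(1, 50_000, 0.02, seed=3)
        for chrom, pos, a_o, a_r in pair.true_variants[:200]:
            assert a_o != a_r
            assert pair.genome_o[chrom][pos] == a_o
            assert pair.genome_r["R" + chrom[1:]][pos] == a_r

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"he_spec": syn.HESpec(1, 0.5), "chrom_length": 50_000},  # < 10 windows
            {"divergence_snp_rate": 0.5},
        ],
    )
    def test_degenerate_inputs_rejected(self, kwargs):
        args = {
            "n_chromosomes": 1,
            "chrom_length": 120_000,
            "divergence_snp_rate": 0.01,
            "seed": 0,
        }
        args.update(kwargs)
        with pytest.raises(ValueError):
            syn.simulate_allotetraploid(**args)

    def test_breakpoint_fraction_bounds(self):
        with pytest.raises(ValueError):
            syn.HESpec(1, 1.5)

    def test_seed_determinism(self):
        a = syn.make_subgenome_pair(2, 30_000, 0.01, seed=7)
        b = syn.make_subgenome_pair(2, 30_000, 0.01, seed=7)
        assert a.genome_o.chromosomes == b.genome_o.chromosomes
        assert a.true_variants == b.true_variants


class TestF2:
    @pytest.fixture(scope="class")
    def parents(self):
        genome = Genome({"c1": syn.random_sequence(50_000, np.random.default_rng(0)),
                         "c2": syn.random_sequence(50_000, np.random.default_rng(1))})
        parent2, positions = syn.simulate_parent_accessions(genome, 30, seed=5)
        return genome, parent2, positions

    def test_zero_crossovers_gives_constant_genotypes(self, parents):
        genome, parent2, positions = parents
        cohort, xo = syn.simulate_f2(genome, parent2, positions, 20, 0.0, 30.0, seed=2)
        for chrom in genome.names:
            idx = np.flatnonzero((cohort.markers["chromosome"] == chrom).to_numpy())
            per_chrom = cohort.genotypes[:, idx]
            assert (per_chrom == per_chrom[:, :1]).all()
        assert all(len(pos) == 0 for plant in xo.values() for pos in plant.values())

    def test_mean_crossovers_matches_poisson(self, parents):
        genome, parent2, positions = parents
        rate = 1.5
        _, xo = syn.simulate_f2(genome, parent2, positions, 50, rate, 30.0, seed=9)
        counts = [len(pos) for plant in xo.values() for pos in plant.values()]
        # two gametes per plant -> mean 2 * rate per chromosome
        mean, n = np.mean(counts), len(counts)
        assert abs(mean - 2 * rate) < 3 * np.sqrt(2 * rate / n)

    def test_unlinked_markers_independent(self, parents):
        genome, parent2, positions = parents
        single = {"c1": positions["c1"][:1], "c2": positions["c2"][:1]}
        cohort, _ = syn.simulate_f2(genome, parent2, single, 500, 1.0, 30.0, seed=13)
        g1, g2 = cohort.genotypes[:, 0], cohort.genotypes[:, 1]
        table = pd.crosstab(g1, g2).to_numpy()
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_genotypes_follow_mendelian_ratio(self, parents):
        genome, parent2, positions = parents
        cohort, _ = syn.simulate_f2(genome, parent2, positions, 200, 1.5, 30.0, seed=3)
        frac_het = (cohort.genotypes == 1).mean()
        assert abs(frac_het - 0.5) < 0.05

    def test_unsorted_markers_rejected(self, parents):
        genome, parent2, positions = parents
        bad = {"c1": positions["c1"][::-1]}
        with pytest.raises(ValueError):
            syn.simulate_f2(genome, parent2, bad, 5, 1.0, 30.0, seed=0)

    def test_identical_parents_rejected(self, parents):
        genome, _, positions = parents
        with pytest.raises(ValueError):
            syn.simulate_f2(genome, genome, positions, 5, 1.0, 30.0, seed=0)


class TestCoverage:
    def test_zero_cross_mapping_leaves_off_target_empty(self, he_system):
        _, tet, truth = he_system
        track = syn.simulate_parental_coverage(
            tet, "O", cross_mapping_rate=0.0, seed=1, he_breakpoints=truth.he_breakpoints
        )
        for chrom, values in track.values.items():
            src = syn.window_sources(tet, track.window_size, truth.he_breakpoints)[chrom]
            assert (values[src == "R"] == 0).all()
            if (src == "O").any():
                assert (values[src == "O"] > 0).any()

    def test_he_chromosome_steps_at_truth_breakpoint(self, he_system):
        _, tet, truth = he_system
        track = syn.simulate_parental_coverage(
            tet, "O", depth_mean=30, cross_mapping_rate=0.02, seed=2,
            he_breakpoints=truth.he_breakpoints,
        )
        values = track.values["O2_R2"]
        # maximal absolute step of the windowed track sits at the breakpoint
        step = int(np.argmax(np.abs(np.diff(values)))) + 1
        bp_window = truth.breakpoint_of("O2_R2") // track.window_size
        assert abs(step - bp_window) <= 1

    def test_on_target_depth_matches_poisson_mean(self):
        pair, tet, _ = syn.simulate_allotetraploid(1, 500_000, 0.01, seed=4)
        track = syn.simulate_parental_coverage(tet, "R", depth_mean=30, seed=5)
        values = track.values["R1"]
        assert abs(values.mean() - 30) < 3 * np.sqrt(30 / values.size)

    def test_window_size_larger_than_chromosome_rejected(self, he_system):
        _, tet, _ = he_system
        with pytest.raises(ValueError):
            syn.simulate_parental_coverage(tet, "O", window_size=10_000_000)


class TestContigs:
    def test_cutting_conserves_sequence(self, he_system):
        _, tet, _ = he_system
        contigs, _ = syn.make_chimeric_contigs(tet, 7, 0, seed=0)
        assert contigs.total_length() == tet.total_length()
        # each contig maps contiguously to one chromosome
        assert all(len(segs) == 1 for segs in contigs.segments.values())

    def test_planted_chimeras_recorded_and_cross_subgenome(self, he_system):
        _, tet, _ = he_system
        contigs, truth = syn.make_chimeric_contigs(tet, 10, 5, seed=3)
        assert len(truth.chimera_junctions) == 5
        for j in truth.chimera_junctions:
            segs = contigs.segments[j.contig]
            assert len(segs) == 2
            assert segs[0][0][0] != segs[1][0][0]  # O- and R-derived halves
            assert segs[0][2] - segs[0][1] == j.position

    def test_chimera_halves_match_source_sequences(self, he_system):
        _, tet, _ = he_system
        contigs, truth = syn.make_chimeric_contigs(tet, 10, 2, seed=4)
        j = truth.chimera_junctions[0]
        (c1, s1, e1), (c2, s2, e2) = contigs.segments[j.contig]
        seq = contigs.sequences[j.contig]
        assert seq[: j.position] == tet[c1][s1:e1]
        assert seq[j.position :] == tet[c2][s2:e2]

    def test_too_many_chimeras_rejected(self, he_system):
        _, tet, _ = he_system
        with pytest.raises(ValueError):
            syn.make_chimeric_contigs(tet, 2, 100, seed=0)


class TestHiC:
    def test_zero_trans_fraction_all_cis(self, he_system):
        _, tet, _ = he_system
        pairs = syn.simulate_hic_pairs(tet, 5000, trans_fraction=0.0, seed=6)
        assert (pairs["chrom1"] == pairs["chrom2"]).all()

    def test_decay_slope_matches_exponent(self):
        genome = Genome({"c1": "A" * 2_000_000})
        pairs = syn.simulate_hic_pairs(
            genome, 100_000, decay_exponent=1.0, trans_fraction=0.0, seed=7
        )
        sep = np.abs(pairs["pos1"] - pairs["pos2"]).to_numpy()
        sep = sep[sep > 0]
        bins = np.logspace(1, 6, 26)
        counts, edges = np.histogram(sep, bins=bins)
        centers = np.sqrt(edges[:-1] * edges[1:])
        widths = np.diff(edges)
        keep = counts > 50
        slope = np.polyfit(np.log(centers[keep]), np.log(counts[keep] / widths[keep]), 1)[0]
        assert abs(slope - (-1.0)) < 0.15

    def test_invalid_pair_count_rejected(self, he_system):
        _, tet, _ = he_system
        with pytest.raises(ValueError):
            syn.simulate_hic_pairs(tet, 0, seed=0)

    def test_seed_determinism(self, he_system):
        _, tet, _ = he_system
        a = syn.simulate_hic_pairs(tet, 1000, seed=9)
        b = syn.simulate_hic_pairs(tet, 1000, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestQuartetSites:
    def test_outgroup_always_ancestral(self):
        g = syn.simulate_quartet_sites(5000, seed=0)
        assert (g["O"] == 0).all()

    def test_null_is_abba_baba_symmetric(self):
        g = syn.simulate_quartet_sites(200_000, introgression_fraction=0.0, seed=1)
        p1, p2, p3 = (g[k][0] for k in ("P1", "P2", "P3"))
        abba = ((p1 == 0) & (p2 == 1) & (p3 == 1)).sum()
        baba = ((p1 == 1) & (p2 == 0) & (p3 == 1)).sum()
        assert abs(abba - baba) < 3 * np.sqrt(abba + baba)


def test_n_windows_rounds_up():
    assert n_windows(25_000, 10_000) == 3
    assert n_windows(30_000, 10_000) == 3
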