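"""Unit behaviour of the genetic-map operations on small constructed inputs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allopolyphase import genetic_map as gm


def make_table(states, contig="tig1", positions=None):
    states = np.asarray(states, dtype=float)
    positions = positions if positions is not None else list(range(states.shape[0]))
    meta = pd.DataFrame({"contig": contig, "position": positions})
    plants = [f"p{i}" for i in range(states.shape[1])]
    return gm.MarkerStateTable(states, meta, plants)


class TestMarkerDB:
    def test_only_homozygous_alt_snps_retained(self):
        records = [
            ("c1", 10, "A", "G", 1),   # heterozygous
            ("c1", 20, "T", "G", 2),   # homozygous-alternative SNP: kept
            ("c1", 5, "C", "C", 0),    # hom-ref
            ("c1", 30, "A", "AT", 2),  # indel
            ("c2", 1, "G", "C", 2),
        ]
        db = gm.build_marker_db(records)
        assert list(db.records["position"]) == [20, 1]
        assert list(db.records["contig"]) == ["c1", "c2"]

    def test_empty_input_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            db = gm.build_marker_db([])
        assert len(db) == 0
        assert "no homozygous" in caplog.text

    def test_synthetic_f0_recovers_planted_positions(self, map_system):
        tet = map_system["tetraploid"]
        parent2 = map_system["parent2"]
        positions = map_system["marker_positions"]
        records = []
        for chrom in tet.names:
            for p in positions[chrom]:
                records.append((chrom, int(p), tet[chrom][p], parent2[chrom][p], 2))
        db = gm.build_marker_db(records)
        for chrom in tet.names:
            got = db.records.loc[db.records["contig"] == chrom, "position"].to_numpy()
            assert np.array_equal(got, np.sort(positions[chrom]))


class TestCallStates:
    def test_state_coding_rules(self):
        db = gm.build_marker_db([("c1", 10, "A", "G", 2), ("c1", 20, "T", "C", 2)])
        variants = {"plantA": {("c1", 10): 1}, "plantB": {("c1", 10): 2, ("c1", 20): 0}}
        depths = {
            "plantA": {("c1", 10): 30, ("c1", 20): 0},
            "plantB": {("c1", 10): 30, ("c1", 20): 30},
        }
        table = gm.call_marker_states(db, variants, depths)
        col_a = table.states[:, table.plants.index("plantA")]
        col_b = table.states[:, table.plants.index("plantB")]
        assert col_a[0] == 0        # het -> 0
        assert np.isnan(col_a[1])   # uncovered -> missing
        assert col_b[0] == 1        # hom-alt -> +1
        assert col_b[1] == -1       # covered, no call -> reference homozygote

    def test_plant_without_depth_all_missing(self, caplog):
        db = gm.build_marker_db([("c1", 10, "A", "G", 2)])
        with caplog.at_level("WARNING"):
            table = gm.call_marker_states(db, {"p1": {}}, {})
        assert np.isnan(table.states).all()

    def test_cohort_states_match_planted_genotypes(self, map_system):
        cohort = map_system["cohort"]
        table = gm.marker_states_from_cohort(cohort)
        expected = cohort.genotypes.T - 1.0
        known = ~np.isnan(table.states)
        agreement = (table.states[known] == expected[known]).mean()
        assert agreement == 1.0
        assert known.mean() > 0.99  # depth 30 rarely dips below 4


class TestFilter:
    def test_missingness_rule_is_strict_majority(self):
        n = 50
        row_keep = [-1] * 25 + [np.nan] * 25        # exactly half missing: kept
        row_drop = [-1] * 24 + [np.nan] * 26        # more than half: dropped
        table = make_table(np.array([row_keep, row_drop]))
        kept, log = gm.filter_markers(table, chi2_threshold=np.inf)
        assert kept.n_markers == 1
        assert list(log["reason"]) == ["missingness"]

    def test_segregation_chi2_rule(self):
        balanced = [-1] * 12 + [0] * 26 + [1] * 12  # chi2 ~ 0.08
        distorted = [-1] * 50                        # chi2 = 150
        table = make_table(np.array([balanced, distorted]))
        kept, log = gm.filter_markers(table)
        assert kept.n_markers == 1
        row = log.iloc[0]
        assert row["reason"] == "segregation"
        assert row["chi2"] == pytest.approx(150.0)

    def test_filtering_is_idempotent(self, map_tables):
        filtered, _ = map_tables
        again, log = gm.filter_markers(filtered)
        assert again.n_markers == filtered.n_markers
        assert len(log) == 0

    def test_all_markers_removed_raises(self):
        table = make_table(np.full((3, 10), np.nan))
        with pytest.raises(ValueError):
            gm.filter_markers(table)

    def test_critical_value_matches_threshold(self):
        assert round(gm.segregation_chi2_critical(), 2) == 5.99


class TestIntervalRecombinations:
    def test_identical_vectors_zero_events(self):
        s = np.array([-1.0, 0, 1, 0, -1])
        events, informative, rate = gm.count_interval_recombinations(s, s)
        assert (events, informative, rate) == (0, 5, 0.0)

    def test_double_recombinant_counts_two_events(self):
        s1 = np.array([-1.0] + [0.0] * 49)
        s2 = np.array([1.0] + [0.0] * 49)
        events, informative, rate = gm.count_interval_recombinations(s1, s2)
        assert events == 2
        assert informative == 50
        assert rate == pytest.approx(2.0)

    def test_missing_pairs_excluded(self):
        s1 = np.array([1.0, np.nan, 0.0])
        s2 = np.array([0.0, 1.0, np.nan])
        events, informative, rate = gm.count_interval_recombinations(s1, s2)
        assert (events, informative) == (1, 1)
        assert rate == pytest.approx(50.0)

    def test_no_informative_plants_gives_nan_rate(self):
        s1 = np.array([np.nan, 1.0])
        s2 = np.array([0.0, np.nan])
        _, informative, rate = gm.count_interval_recombinations(s1, s2)
        assert informative == 0
        assert np.isnan(rate)


class TestMisassemblyDetection:
    def test_exactly_two_events_not_flagged(self):
        # two markers differing by a single -1 <-> +1 plant: 2 events
        states = np.array(
            [[-1.0] + [0.0] * 49, [1.0] + [0.0] * 49]
        )
        table = make_table(states, positions=[100, 200])
        assert len(gm.detect_misassemblies(table)) == 0

    def test_three_events_flagged(self):
        states = np.array(
            [[-1.0, -1.0, 1.0] + [0.0] * 47, [1.0, 0.0, 1.0] + [0.0] * 47]
        )
        table = make_table(states, positions=[100, 200])
        hits = gm.detect_misassemblies(table)
        assert len(hits) == 1
        assert hits.iloc[0]["events"] == 3

    def test_intervals_do_not_span_contigs(self):
        states = np.array([[-1.0] * 10, [1.0] * 10])
        meta = pd.DataFrame({"contig": ["a", "b"], "position": [0, 0]})
        table = gm.MarkerStateTable(states, meta, [f"p{i}" for i in range(10)])
        assert len(gm.detect_misassemblies(table)) == 0

    def test_noisy_marker_removal_drops_double_flagged(self):
        # middle marker flips against both neighbours -> two flagged intervals
        states = np.array(
            [[-1.0] * 50, [1.0] * 25 + [-1.0] * 25, [-1.0] * 50]
        )
        table = make_table(states, positions=[0, 10, 20])
        flagged = gm.detect_misassemblies(table)
        assert len(flagged) == 2
        cleaned = gm.remove_noisy_markers(table, flagged)
        assert cleaned.n_markers == 2
        assert list(cleaned.meta["position"]) == [0, 20]


class TestContigCoding:
    @pytest.mark.parametrize(
        "mean,expected",
        [
            (-1.0, -1.0),
            (-0.8, -1.0),   # interval end included
            (0.8, 1.0),
            (1.0, 1.0),
            (-0.2, 0.0),
            (0.0, 0.0),
            (0.2, 0.0),
            (0.5, np.nan),  # ambiguous band
            (-0.5, np.nan),
            (np.nan, np.nan),
        ],
    )
    def test_interval_rules(self, mean, expected):
        got = gm.code_contig_mean(mean)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_codes_average_over_contig_markers(self):
        states = np.array([[1.0, -1.0], [1.0, -1.0], [0.0, -1.0]])
        meta = pd.DataFrame({"contig": ["a", "a", "a"], "position": [0, 1, 2]})
        table = gm.MarkerStateTable(states, meta, ["p1", "p2"])
        codes = gm.code_contigs(table)
        assert codes.means[0, 0] == pytest.approx(2 / 3)
        assert np.isnan(codes.codes[0, 0])  # 0.67 falls in the ambiguous band
        assert codes.codes[0, 1] == -1.0

    def test_letter_rendering(self):
        states = np.array([[1.0, -1.0, 0.0, np.nan]])
        meta = pd.DataFrame({"contig": ["a"], "position": [0]})
        table = gm.MarkerStateTable(states, meta, list("wxyz"))
        letters = gm.code_contigs(table).to_letters()
        assert list(letters.iloc[0]) == ["B", "A", "X", "-"]


class TestGrouping:
    def test_single_contig_single_group(self):
        states = np.array([[1.0] * 10])
        meta = pd.DataFrame({"contig": ["a"], "position": [0]})
        codes = gm.code_contigs(gm.MarkerStateTable(states, meta, [f"p{i}" for i in range(10)]))
        groups = gm.group_and_order(codes)
        assert len(groups) == 1
        assert groups[0].contigs == ["a"]

    def test_linked_join_unlinked_split(self):
        rng = np.random.default_rng(0)
        g1 = rng.integers(0, 3, 200) - 1.0
        g2 = g1.copy()
        flip = rng.random(200) < 0.02  # rf ~ 0.02 partner
        g2[flip] = rng.integers(0, 3, flip.sum()) - 1.0
        g3 = rng.integers(0, 3, 200) - 1.0  # unlinked
        states = np.stack([g1, g2, g3])
        meta = pd.DataFrame({"contig": ["a", "b", "c"], "position": [0, 0, 0]})
        codes = gm.code_contigs(
            gm.MarkerStateTable(states, meta, [f"p{i}" for i in range(200)])
        )
        groups = gm.group_and_order(codes)
        members = {frozenset(g.contigs) for g in groups}
        assert frozenset({"a", "b"}) in members
        assert frozenset({"c"}) in members

    def test_zero_information_contig_is_flagged_singleton(self):
        states = np.array([[1.0] * 10, [np.nan] * 10])
        meta = pd.DataFrame({"contig": ["a", "b"], "position": [0, 0]})
        codes = gm.code_contigs(gm.MarkerStateTable(states, meta, [f"p{i}" for i in range(10)]))
        groups = gm.group_and_order(codes)
        flagged = [g for g in groups if g.singleton_no_data]
        assert len(flagged) == 1
        assert flagged[0].contigs == ["b"]

    def test_plain_single_linkage_matches_brute_force_components(self, map_tables):
        """Oracle check: with the gates disabled, grouping is exactly the
        connected components of the thresholded rf graph."""
        _, codes = map_tables
        groups = gm.group_and_order(
            codes,
            rf_link_threshold=0.25,
            linkage_alpha=1.0,
            merge_alpha=0.0,
            end_merge_alpha=0.0,
            n_groups_target=None,
        )
        link = gm.pairwise_linkage(codes)
        m = len(link.contigs)
        # brute-force union-find over the thresholded graph
        parent = list(range(m))
        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x
        for i in range(m):
            for j in range(i + 1, m):
                if np.isfinite(link.rf[i, j]) and link.rf[i, j] < 0.25:
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(m):
            oracle.setdefault(find(i), set()).add(link.contigs[i])
        got = {frozenset(g.contigs) for g in groups}
        assert got == {frozenset(v) for v in oracle.values()}

    def test_rf_estimator_consistency(self):
        """rf -> 0 for identical markers and -> 0.5 for unlinked, at n=500."""
        rng = np.random.default_rng(42)
        g = rng.integers(0, 3, 500) - 1.0
        unlinked = rng.integers(0, 3, 500) - 1.0
        states = np.stack([g, g, unlinked])
        meta = pd.DataFrame({"contig": ["a", "b", "c"], "position": [0, 0, 0]})
        codes = gm.code_contigs(
            gm.MarkerStateTable(states, meta, [f"p{i}" for i in range(500)])
        )
        link = gm.pairwise_linkage(codes)
        i = {c: k for k, c in enumerate(link.contigs)}
        assert link.rf[i["a"], i["b"]] < 0.05
        assert abs(link.rf[i["a"], i["c"]] - 0.5) < 0.05
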