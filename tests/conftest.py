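"""Shared fixtures: small synthetic systems reused across test modules."""

import numpy as np
import pytest

from allopolyphase import genetic_map as gm
from allopolyphase import synthetic as syn


@pytest.fixture(scope="session")
def he_system():
    """A 4-pair tetraploid with one reciprocal exchange on pair 2."""
    pair, tetraploid, truth = syn.simulate_allotetraploid(
        4, 500_000, 0.01, he_spec=syn.HESpec(2, 0.5), seed=11
    )
    return pair, tetraploid, truth


@pytest.fixture(scope="session")
def map_system():
    """The canonical 16-chromosome mapping cohort (50 plants, rate 1.5)."""
    pair, tetraploid, truth = syn.simulate_allotetraploid(8, 300_000, 0.01, seed=1)
    parent2, marker_positions = syn.simulate_parent_accessions(tetraploid, 50, seed=1001)
    cohort, crossovers = syn.simulate_f2(
        tetraploid, parent2, marker_positions, 50, 1.5, 30.0, seed=2001
    )
    truth.crossovers = crossovers
    contigs, truth = syn.make_chimeric_contigs(tetraploid, 10, 0, seed=1, truth=truth)
    contig_map = syn.markers_on_contigs(marker_positions, contigs)
    return {
        "tetraploid": tetraploid,
        "parent2": parent2,
        "marker_positions": marker_positions,
        "cohort": cohort,
        "truth": truth,
        "contigs": contigs,
        "contig_map": contig_map,
    }


@pytest.fixture(scope="session")
def map_tables(map_system):
    table = gm.marker_states_from_cohort(
        map_system["cohort"], contig_map=map_system["contig_map"]
    )
    filtered, _ = gm.filter_markers(table)
    codes = gm.code_contigs(filtered)
    return filtered, codes


def chimera_run(seed, n_pairs=3, chrom_length=2_000_000, markers=20_000, n_chimeras=5):
    """One misassembly-detection study: dense markers, planted chimeras."""
    pair, tetraploid, truth = syn.simulate_allotetraploid(
        n_pairs, chrom_length, 0.01, seed=seed
    )
    contigs, truth = syn.make_chimeric_contigs(
        tetraploid, 10, n_chimeras, seed=seed + 500, truth=truth
    )
    parent2, marker_positions = syn.simulate_parent_accessions(
        tetraploid, markers, seed=seed + 1000
    )
    cohort, _ = syn.simulate_f2(
        tetraploid, parent2, marker_positions, 50, 1.5, 30.0, seed=seed + 2000
    )
    contig_map = syn.markers_on_contigs(marker_positions, contigs)
    table = gm.marker_states_from_cohort(cohort, contig_map=contig_map)
    filtered, _ = gm.filter_markers(table)
    return filtered, truth, contigs


def chromosome_of(contigs):
    """Primary source chromosome of every contig."""
    return {name: segs[0][0] for name, segs in contigs.segments.items()}
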