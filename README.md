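# allopolyphase

Subgenome-resolved assembly checking and population genomics for recent
allotetraploids, modelled on the analysis of *Capsella bursa-pastoris* — a
selfing weed carrying two subgenomes, **O** (from *C. orientalis*) and **R**
(from *C. grandiflora/rubella*), that diverged about 1 Mya and are therefore
similar enough to confuse assemblers, read mappers and annotators.

The package implements the bespoke computational steps such an assembly
project needs, each testable end to end on a synthetic allotetraploid with
full ground truth generated in-repo:

- **`synthetic`** — the generator: two substitution-diverged subgenomes, a
  tetraploid reference with an optional reciprocal homeologous exchange
  (HE, producing hybrid chromosomes named `O7_R7`/`R7_O7`), an F2 mapping
  cohort with Poisson crossovers, parental read-coverage tracks, chimeric
  contig sets, Hi-C contact pairs with power-law distance decay, and
  planted homeologous gene pairs.
- **`genetic_map`** — F2 marker states (−1/0/+1/missing), missingness and
  1:2:1 Pearson χ² filtering (threshold 5.99 = χ²₀.₀₅, df 2), misassembly
  detection from impossible recombination between adjacent markers,
  A/B/X contig coding, linkage grouping and within-group ordering.
- **`subgenome`** — window-wise parental coverage log-ratios, change-point
  segmentation into O/R segments, HE breakpoint calls, and an exact-k-mer
  read-assignment simulation validating the combined-reference approach.
- **`homeolog`** — homeolog pairing by reciprocal best similarity with a
  positional (ordinal-rank) tie-break, an interval-constrained rescue round
  for unpaired genes, ORF validation, and systematic names of the form
  `Cbp.O1.g00001000.AT1G02140_O`.
- **`popgen`** — per-chromosome-arm pseudoalignments (depth < 4 → `N`,
  heterozygotes → IUPAC codes), Patterson's D (ABBA–BABA) with a block
  jackknife and the f4-ratio admixture fraction.
- **`hic`** — contact binning, empirical distance decay, junction
  observed/expected scoring, and the simulated-translocation control that
  distinguishes a real chromosome join from an artifactual one.

## The core statistics

A physically joined but genetically unlinked sequence betrays itself in an
F2: between adjacent markers the apparent recombination count
`events = Σ_plants |g₁ − g₂|` (genotypes g ∈ {−1, 0, 1}; a −1↔+1 change
counts one event per homologous chromosome) gives a rate per 100
chromosomes of `100 · events / (2 · n)`. Linked markers a few kb apart show
rates far below 1; unlinked markers show ≈ 35–40 — an impossible value that
flags a chimeric join (rule: more than two events between adjacent markers).

For linkage grouping, pairwise recombination fractions are estimated
margin-conditionally, `rf = 1 − √(1 − 0.75·events/E₀)` with `E₀` the
independence expectation given observed genotype margins, so unlinked
contigs converge to rf = 0.5; grouping proceeds from high-stringency cores
to a closure against the known haploid chromosome number (see
`docs/methods.md`).

Patterson's D uses derived-allele frequencies with the outgroup ancestral:
`D = Σ[(1−p₁)p₂p₃ − p₁(1−p₂)p₃] / Σ[(1−p₁)p₂p₃ + p₁(1−p₂)p₃]`, with a
delete-one block jackknife for Z and the f4-ratio
`Σ[(1−p₁)p₂p₃b − p₁(1−p₂)p₃b] / Σ[(1−p₁)p₃ap₃b − p₁(1−p₃a)p₃b]`
estimating the introgressed fraction of P2.

## Worked example

```python
from allopolyphase import synthetic as syn, genetic_map as gm, subgenome as sg, hic

pair, tet, truth = syn.simulate_allotetraploid(
    8, 300_000, 0.01, he_spec=syn.HESpec(7, 0.5), seed=1)
parent2, markers = syn.simulate_parent_accessions(tet, 50, seed=1001)
cohort, _ = syn.simulate_f2(tet, parent2, markers, 50, 1.5, 30.0, seed=2001)
contigs, truth = syn.make_chimeric_contigs(tet, 10, 0, seed=1, truth=truth)
table = gm.marker_states_from_cohort(
    cohort, contig_map=syn.markers_on_contigs(markers, contigs))
filtered, log = gm.filter_markers(table)
codes = gm.code_contigs(filtered)
groups = gm.group_and_order(codes, n_groups_target=16)
print(f"markers kept: {filtered.n_markers}/{table.n_markers} "
      f"({int((log.reason == 'segregation').sum())} segregation-distorted removed)")
print("linkage groups:", len(groups),
      "sizes:", sorted(len(g.contigs) for g in groups))

track_o = syn.simulate_parental_coverage(tet, "O", depth_mean=30, seed=3001,
                                         he_breakpoints=truth.he_breakpoints)
track_r = syn.simulate_parental_coverage(tet, "R", depth_mean=30, seed=3002,
                                         he_breakpoints=truth.he_breakpoints)
for prof in sg.profiles_from_tracks(track_o, track_r):
    call = sg.call_subgenome(prof)
    if call.label == "hybrid":
        print(f"{call.chromosome}: hybrid, breakpoint {call.breakpoints} "
              f"(truth {truth.breakpoint_of(call.chromosome)}), "
              f"confidence {call.confidence:.2f}")

pairs = syn.simulate_hic_pairs(tet, 100_000, seed=4001)
(ha, ba), (hb, bb) = truth.he_breakpoints
m = hic.bin_contacts(pairs, 20_000, tet.lengths()).cis[ha]
s = hic.junction_score(m, ba, flank=100_000)
print(f"Hi-C junction at {ha}:{ba}: observed/expected = {s.ratio:.2f} -> {s.verdict}")
lift = hic.liftover_translocation_pairs(pairs, ha, hb, ba, bb)
m2 = hic.bin_contacts(lift, 20_000, tet.lengths()).cis[ha]
s2 = hic.junction_score(m2, ba, flank=100_000)
print(f"same junction on translocated reference: ratio = {s2.ratio:.2f} -> {s2.verdict}")
```

prints:

```
markers kept: 756/800 (44 segregation-distorted removed)
linkage groups: 16 sizes: [9, 9, 10, 10, 10, 10, 10, 10, 10, 10, 10, 10, 10, 10, 10, 10]
O7_R7: hybrid, breakpoint [150000] (truth 150000), confidence 1.00
R7_O7: hybrid, breakpoint [150000] (truth 150000), confidence 1.00
Hi-C junction at O7_R7:150000: observed/expected = 0.93 -> supported
same junction on translocated reference: ratio = 0.33 -> gap
```

Reading: the 1:2:1 segregation filter removed 44 of 800 markers; the 16
linkage groups match the haploid chromosome number, each drawing its
contigs from a single chromosome; the coverage caller labels both hybrid
chromosomes and places the exchange breakpoint exactly at the planted
150 kb; and the Hi-C junction score supports the hybrid join on the true
reference (ratio 0.93) while the artificially translocated reference shows
the contact gap (ratio 0.33) expected when the reference disagrees
structurally with the sequenced genome.

A command-line interface wraps the same steps
(`allopolyphase simulate | map | subgenome | homeolog | popgen | hic`);
`allopolyphase simulate --outdir DIR --seed N` writes FASTA, VCF, BED-graph
coverage, Hi-C pairs and a YAML truth file for a full synthetic system.

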