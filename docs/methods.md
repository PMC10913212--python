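# Methods

## The synthetic allotetraploid

All pipelines are exercised on a simulated allotetraploid built from a
random ancestral sequence. The two subgenomes, O and R, diverge by
substitution only, at a per-base SNP rate (default 0.01, the order of
divergence expected from parents separated by roughly a million years in a
small-genome crucifer). Substitution-only divergence keeps homeologous
coordinates identical, which makes every piece of ground truth — planted
variants, chimera junctions, exchange breakpoints, homeolog pairs — exact
rather than approximate. The lineage-specific-fragment analogue (a region
present in R with no O homolog) is therefore implemented by overwriting the
homeologous O interval with unrelated random sequence rather than by a
literal deletion; the biological semantics (no homologous counterpart) are
identical and the coordinate frame survives.

A reciprocal homeologous exchange is applied to one chromosome pair: the
two products keep their own subgenome up to the breakpoint and switch
source after it, giving hybrid chromosomes (`O7_R7`, `R7_O7`) whose two
breakpoints are mirror images — the invariant every downstream HE test
relies on.

The F2 cohort assumes disomic inheritance (each of the 2n chromosomes is an
independent linkage group, as in a functionally diploid allotetraploid) and
pure Poisson crossovers with no interference; the misassembly rule counts
events between *adjacent* markers, where interference is irrelevant.
Marker depths are Poisson; there is no sequencing-error or read-level
model, no repeat families and no centromere structure. Passing tests
therefore demonstrate the statistical logic of each procedure, not its
robustness to mapping artefacts in repeat-rich regions — the step the
original analysis handled by manual curation and which is explicitly out of
scope here.

Default scale for the mapping experiments: 8 homeologous pairs (16
chromosomes) of 300 kb, ~50 markers and 10 contigs per chromosome, 50 F2
plants, Poisson(1.5) crossovers per chromosome per meiosis, mean depth 30.
These sizes run the whole pipeline in under a second per seed while keeping
every statistic in the regime the procedures were designed for.

## Marker states, filtering, misassembly detection

States follow the codominant F2 convention: −1 reference homozygote, 0
heterozygote, +1 alternative homozygote, missing when depth < 4. Markers
unidentified in more than half of the plants are removed, as are markers
whose (−1, 0, +1) counts fail the Pearson χ² test against 1:2:1 above 5.99
(the α = 0.05 critical value at two degrees of freedom, computed by
`scipy.stats.chi2.ppf`). Filtering is idempotent.

Between adjacent markers the apparent recombination count is
`Σ_plants |g₁ − g₂|` over pairwise-complete plants; a −1↔+1 change counts
two events (one per homologous chromosome), and the rate per 100
chromosomes is `100·events/(2n)`. Unlinked markers give an expected rate of
37.5 (not 50: the double-recombinant heterozygote pattern is invisible to
this statistic), which is what makes the misassembly signature — strictly
more than two events between markers a few hundred bases apart —
unambiguous.

One interaction deserves note: the segregation filter removes *blocks* of
linked markers when a chromosomal region drifts past the χ² threshold
(about 5 % of regions, since all markers of a region share the same
segregation draw). The resulting wide physical gaps have genuine genetic
length, so the raw ">2 events" rule would flag them. `detect_misassemblies`
therefore accepts an optional rate floor (`min_rate_per_100`, canonical
value 15): true mis-joins sit near the unlinked expectation of ~37, linked
gaps in single digits, so the floor separates them with an order of
magnitude to spare. A junction whose entire flank was removed by the filter
is undetectable by map evidence — the same sequence the original workflow
dropped from the assembly — and the acceptance study accounts misses that
way (observed in ~2 % of planted junctions).

The misassembly study uses a denser fixture than the mapping default: 3
homeologous pairs of 2 Mb with markers every ~100 bp, reproducing the real
regime where adjacent-marker genetic distance (⋘ 1 event expected across
50 plants) is tiny compared with the flag threshold.

## Contig coding and linkage grouping

Per contig and plant, the mean of non-missing marker states is coded A
(mean in [−1, −0.8]), B ([0.8, 1]), X ([−0.2, 0.2]) or missing (the
ambiguous bands), interval ends included.

Pairwise recombination fractions between contigs come from the event count
calibrated against its independence expectation *given the observed
genotype margins*: `rf = 1 − √(1 − 0.75·events/E₀)`. The margin
conditioning is essential, not cosmetic: two chromosomes that happen to
share a segregation skew (say both heterozygote-rich in the same cohort)
depress the raw event count between *every* pair of their contigs, and the
uncorrected estimator then manufactures genome-scale pseudo-linkage.
Linkage evidence per pair is the Pearson χ² test of independence on the
3×3 joint genotype table (margin-conditional by construction).

Grouping proceeds in three stages of decreasing stringency, because a
50-plant F2 simply does not contain enough information to classify every
contig pair in one pass (an unlinked pair produces rf < 0.25 with
probability ~10⁻³, and with ~13 000 pairs tested a handful of such
accidents per run is certain, interleaved with the weakest genuine links):

1. **Cores** — connected components of the graph with rf < 0.25 and
   independence p < 10⁻⁶. Essentially no false edges; chromosomes emerge
   as a few fragments each.
2. **Gated merging** — single-linkage merges accepted when the best pair's
   p-value times the number of cross pairs is below 10⁻³ (a per-component
   multiplicity correction), or when the best link joins the *terminal*
   contigs of both fragments' internal orderings at p·4 < 0.02 — a genuine
   chain join is always end-to-end, an accidental minimum rarely is.
3. **Closure** — when the haploid chromosome number is supplied
   (`n_groups_target`, the standard practice of closing a genetic map
   against the known karyotype), remaining fragments are merged in order
   of linkage significance, with rf eligibility relaxed to 0.45, until the
   target is reached. Merges that would exceed the average
   contigs-per-group implied by the target are rejected throughout: chance
   pseudo-linkage characteristically tries to fuse two already-complete
   chromosomes, and the size cap blocks exactly that.

Measured on 50 independent cohorts at the default scale, the procedure
returns 16 groups in 49/50 runs and 16 fully chromosome-pure groups in
44/50; the impure runs misplace one or two fragments. Plain single-linkage
thresholding remains available by parameter choice (and is what the
brute-force oracle test checks); at this cohort size it either fragments
chromosomes or fuses them, depending on the threshold.

Within a group, contigs are ordered along the longest path of the minimum
spanning tree of the rf graph, refined by 2-opt segment reversal minimising
the summed adjacent rf; ties break lexicographically, orientation is fixed
by the terminal contig names, and orderings correlate with physical
position at |ρ| ≥ 0.95 in almost every group.

Per-chromosome recombination counts can be taken over contig codes (coarse;
absorbs double crossovers within a contig span) or over the ordered marker
states (`states=` argument), which recovers nearly all crossovers and is
what the expectation checks use.

## Subgenome assignment

Per 10-kb window the caller works on `log2((depth_O + 1)/(depth_R + 1))`.
Binary segmentation minimises within-segment squared error with a
BIC-flavoured acceptance penalty (3·σ̂²·log n, σ̂ from the median absolute
first difference); segments shorter than 5 windows are merged, each segment
is labelled by mean sign, and a chromosome is `hybrid` exactly when both
sources appear. Confidence is the fraction of windows that are unambiguous
(|log-ratio| ≥ 1, i.e. a two-fold contrast) and agree with their segment.
At depth 30 and 5 % cross-mapping the planted exchange breakpoint is
recovered within ±2 windows in 20/20 seeds.

The combined-reference validation assigns error-free simulated reads to the
chromosome sharing the most exact 31-mers, ties unassigned. Its ceiling is
set by arithmetic, not implementation: at 1 % divergence a 150-bp read
carries no diagnostic site with probability 0.99¹⁵⁰ ≈ 0.22 and must tie, so
the correct fraction approaches ~0.78 of all reads (and ~1.0 of assigned
reads); at 5 % divergence and 300-bp reads assignment is essentially
perfect.

## Homeolog pairing, rescue, naming

Similarity is an 11-mer seed + ungapped diagonal scorer (match +1,
mismatch −1, identity over the overlapped stretch) — exact for
substitution-only divergence and deterministic; externally computed tabular
hits can be supplied in the same form. Reciprocal best hits pair first;
remaining one-directional best hits are accepted in order of ordinal-rank
distance along the chromosome (ties by score, then id) when within 10
ranks. The procedure is symmetric in the two subgenomes and no gene joins
two pairs.

Rescue scans the homeologous interval between the partners of the nearest
paired neighbours (one flank suffices at chromosome ends) with the same
scorer; a hit with identity ≥ 0.8 whose matched sequence is a valid ORF
(ATG start, terminal stop, no internal in-frame stop, length ≥ 6 and
divisible by 3) and overlaps no existing gene becomes a new rescue-method
gene model. Genes facing a planted deletion are reported genuinely missing.

Systematic names follow
`Cbp.<chromosome>.g<number, 8 digits>.<At-ortholog>_<method>` with numbers
spaced by 1000; method letters are O (orthogroup-derived correspondence),
B (best-hit) and N (no correspondence, At slot `NA`) — the source format
shows only `_O`, so B and N are this package's declared extensions. Names
parse back exactly.

## Pseudoalignments and introgression statistics

The site list is the union of biallelic SNPs over samples (indels
excluded; conflicting alternative alleles kept and logged). Per sample and
listed site: depth < 4 → N, homozygous alternative → the alternative base,
heterozygous → the two-base IUPAC code, covered without a call → reference.
Rows always have region length, so the multi-FASTA is positionally
homologous by construction.

D uses derived-allele frequencies with the outgroup defining the ancestral
state (outgroup-polymorphic sites masked); heterozygotes contribute 0.5 so
IUPAC rows stay usable. Z comes from a delete-one block jackknife over
contiguous 1000-site blocks. The f4-ratio normalises the D numerator by its
value under complete introgression, with P3's samples split into
independent halves; on the site-class simulator it recovers the planted
introgressed fraction to within a few hundredths. The quartet simulator
places one derived mutation per site on a branch of (((P1,P2),P3),O) with
an incomplete-lineage-sorting class that is exactly ABBA/BABA-symmetric
under the null, so |Z| < 3 in ≥ 95 % of null runs while a 20 % P3→P2
transfer at 50 000 sites gives Z ≫ 3.

## Hi-C junction validation

Pairs are binned at 100 kb by default (20 kb on the small synthetic
genome); cis matrices are symmetric and count each pair twice. The null
expectation is the matrix's own empirical distance decay; a candidate
junction's score is the ratio of observed to expected contacts over the
±flank window. Verdicts: gap below 0.4, supported at or above 0.6. The
thresholds are calibrated on the simulator: at 5 % trans fraction the
trans-noise floor leaves a ratio of 0.20–0.31 at a join that does not exist
in the sequenced genome, while a real join scores 0.78–0.93; separation was
perfect over 20 seeds. The ratio is invariant to uniform scaling of the
matrix, so sequencing depth cancels.

The simulated-translocation control swaps the distal segments of the two
hybrid chromosomes (an involution, restoring pure parental chromosomes in
the synthetic genome) and re-addresses the contact pairs as mapping on the
modified reference would; with equal breakpoints the re-addressing is an
exact renaming because homeologous coordinates coincide.

## Known limitations

- No read-level, error, repeat or centromere modelling; coverage tracks
  are Poisson draws, not mapped reads.
- The grouping closure consumes the karyotype as prior knowledge; without
  it, chromosome counts at n = 50 plants are approximate by one or two
  groups in either direction.
- The group-size cap assumes roughly balanced contigs-per-chromosome; on
  heavily skewed real assemblies it should be widened
  (`max_group_factor`).
- f4-ratio without an explicit P3 sample split falls back to the pooled
  frequency and is mildly biased upward at polymorphic sites.
- The similarity scorer is ungapped; on real (indel-containing) data,
  externally computed hits should be supplied instead.
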