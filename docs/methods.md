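# Methods

## Reads to chimeras

Reads are demultiplexed by exact sample-index match at a configurable
offset (default: read 5′ end), the 3′ adapter
(`GTGTCAGTCACTTCCAGCGG`) is removed at the leftmost qualifying match
(full-length occurrences tolerate one mismatch; suffix–prefix overlaps
must be exact and ≥ 6 nt), reads < 18 nt are dropped with counts, and PCR
duplicates are collapsed by full sequence identity (no UMI model). Stage
accounting is exact: reads in = assigned + unassigned + dropped.

miRNA "reverse mapping" translates a quality-weighted aligner
configuration into an explicit contract: the miRNA 5′ 8-mer must occur in
the read with ≤ 1 mismatch, extended 3′-ward with ≤ 2 further mismatches;
full-length mode requires the whole mature sequence, truncation mode
accepts ≥ 12 nt from the 5′ end (the matched span must end on a matching
base, so trailing mismatches are never absorbed into the miRNA) and
records the missing 3′ bases. Ties are broken by fewest mismatches, then
longest span, then leftmost position; residual ties between miRNAs
(typically seed-family members) are kept as a candidate set and resolved
by a per-read seeded draw, reproducible across runs and insensitive to
read order. Flanks ≥ 18 nt become target fragments: 3′ flank → miR-first,
5′ flank → miR-last; one read may emit both, deduplicated downstream by
(read, orientation).

Target placement models substitutions only (≤ 2 by default): edlib
proposes candidate loci on both strands, each verified and re-scored by
Hamming distance at fixed length; a fragment is kept only when exactly one
best-scoring placement exists. Fragments overlapping annotated miRNA loci
(either strand, ≥ 1 bp) are removed. Indels in target fragments are
handled at the seed-annotation and duplex stages instead, which matches
the small-mismatch unique-hit regime this mapping targets.

### Orientation-rate estimation

The miR-first:miR-last ratio is estimated from the truncation-tolerant
pass restricted to ≤ 1 nt 3′ truncation, not from the full-length pass.
The full-length pass is intrinsically asymmetric for truncated miRNAs: a
3′-truncated miR-last chimera ends the read and can never satisfy the
full-length requirement, while the equivalent miR-first chimera absorbs
one flank base as a mismatch and is still called — inflating the ratio by
roughly the inverse of the full-length fraction. The ≤ 1 nt-truncation
filter keeps the estimator symmetric while excluding the spurious deep
"truncations" (6–10 nt) that random background matches produce, so its
background false-call rate is zero in generator tests. Recall and
specificity metrics are always quoted from the strict full-length pass.

## Interactions

Unique-mapped, same-miRNA, same-strand chimeras with overlapping
coordinates merge by transitive closure (order-independent; verified
against an O(n²) union–find oracle). The ligation site of a cluster is
the modal member 5′ end with ties to the most upstream position on the
strand — the definition is recorded per interaction so it is auditable.
Target regions are 75 nt downstream of the ligation site (strand-aware,
extending beyond the sequenced fragment when needed); clusters of
76–100 nt are instead trimmed symmetrically to 75 (the extra base removed
from the 5′ side when odd), clusters > 100 nt are dropped and counted,
and chromosome-end clipping is flagged. Region labels come from midpoint
overlap with a fixed priority ladder (3′UTR > CDS > 5′UTR > noncoding >
intron > intergenic) to resolve overlapping isoforms deterministically.
Peak support counts overlapping non-chimeric reads, the number of
distinct biological samples contributing them (BC), and a density defined
as the mean over libraries of `(count + 1) / depth × 10⁶`; the
pseudocount precedes scaling, and the per-million scale is a package
choice recorded in output headers (thresholds such as "density ≥ 40" are
applied on this scale).

## Seed taxonomy

Canonical sites are exact string matches of the reverse-complemented seed
in the target region: 8mer = positions 2–8 plus target A opposite
position 1 (the A is required to be A, not complementary), 7mer-m8 =
2–8, 7mer-A1 = 2–7 plus A, 6mer = 2–7; highest class wins, leftmost on
ties. Variants enumerate every single edit of each canonical site:
substitutions (mm8/mm7/mm6 with the miRNA-coordinate position),
single target-base insertions between two seed pairs of 8mer/7mer-m8
sites (bulged target, inserted base recorded), and single target-base
deletions at interior positions (bulged miRNA). A substitution that
leaves a G:U pairing is reported as the canonical class with the wobble
position recorded (a switch demotes wobbles to mismatches for sensitivity
analyses). Candidates are ranked by most seed pairs, then fewest edits,
then proximity to the ligation junction. Variant search runs only when no
canonical site exists, so variants never override canonical calls.

Junction localization reports, per chimera, the canonical match closest
to the junction and the fraction of chimeras with any canonical match in
the 75-nt downstream window versus its upstream mirror, for the true
assignment and for a cyclic-shuffled assignment in which no region keeps
its own interaction's miRNA. With a small catalogue the shuffled control
retains a floor of seed-identity collisions (another chimera may carry
the same seed); tests bound the shuffled downstream fraction rather than
asserting symmetry, mirroring how such controls behave on real data with
skewed miRNA abundances.

## Duplex model

Structures are intermolecular-only, non-branching, non-crossing matchings
between miRNA positions 2..L (position 1 is trimmed; it is buried in AGO
and does not pair) and the target read 3′→5′. The energy model is a
nearest-neighbour stacking table over {AU, UA, GC, CG, GU, UG} with
size-dependent bulge and interior-loop penalties (capped at 15 nt per
strand), terminal penalties on AU/GU closing pairs, and zero duplex
initiation (energies are used comparatively). The shipped table
approximates Turner-style values and is a documented, swappable TSV;
numeric equality with external folding tools is not claimed — correctness
is established against an exhaustive enumeration of all non-crossing
pairings under the same table (exact agreement on hundreds of random
8×9-nt instances), and a unit-cost table turns the DP into a
longest-noncrossing-complementary-subsequence solver, checked against an
independent combinatorial oracle. The loader completes the stack table
via strand-swap symmetry and averages doubly specified entries, so the
table is exactly symmetric.

Constraints are enforced inside the recursion: anchored constraints pin
seed positions to the matched target offsets (canonical sites force the
full matched helix — interpreting the forced positions as anchored at
the annotated site is the only reading consistent with near-total seed
concordance), and required-paired constraints (positions {3,4} or {5,6}
for mismatch/bulged sites, lower-energy run kept) forbid skipping a
required position between consecutive pairs. Constrained optima are
returned even when non-negative; unconstrained folds return the empty
structure at 0 kcal/mol when no stabilizing structure exists. Constrained
MFE is provably ≥ unconstrained MFE, and tests assert it on 1,000 random
pairs. Pairing profiles score 1 for Watson–Crick or G:U pairs; partner
indices are reported in 3′→5′ target coordinates so they increase
monotonically along the miRNA. The kernel is a numba-compiled
O(n·m·W²) dynamic program (~0.3 ms per 22×75 fold).

The shuffled-assignment null re-assigns each region the miRNA of a
different interaction via Sattolo's algorithm (a uniform cyclic
permutation, hence derangement by construction) and compares true versus
shuffled unconstrained MFE distributions with a two-tailed Welch t-test.

## Binding classes

Pairing profiles form a binary matrix over positions 2..Lmax; columns
beyond a shorter miRNA's length are masked out of both distances and
centroid updates rather than imputed. k-means uses ++-style seeding,
best-of-50 restarts, and deterministic seeding; classes are relabelled by
descending mean seed-region pairing so labels are stable across runs and
row orders. The k sweep (3–12) additionally restarts each k from the
previous best centroids plus the worst-fit row, which guarantees inertia
is non-increasing in k; silhouette is reported and k is always a user
decision. On mask-free matrices the implementation agrees with
scikit-learn's KMeans (cross-check in tests). Per-miRNA class enrichment
uses two-sided Fisher exact tests on the 2×2 miRNA-by-class table for
miRNAs with ≥ 50 sites at a fixed P < 10⁻³, with no multiple-testing
correction by default (a Benjamini–Hochberg option exists); scipy's
Fisher test is verified against exact integer-arithmetic hypergeometric
tail enumeration.

## Motif confidence

Per eligible miRNA (≥ 50 chimeras and ≥ 40 sites), every 7-mer's
per-region presence is tested one-sided hypergeometrically against a
background of 5× as many regions drawn without replacement from other
miRNAs' chimeras, excluding same-seed paralogues; three independent
background draws are used and a motif must pass retention in ≥ 2. The
top 25 non-redundant candidates (suppressing Hamming-1 and single-shift
neighbours; candidates must appear in ≥ 10% of the foreground) are
refined into position frequency matrices from their best foreground
occurrence per region (exact preferred, else Hamming-1, leftmost) — this
softening is what gives the information-content floor its statistical
teeth in the null. The match score s is the PFM's mean per-column
probability of the miRNA's reverse-complement base at the best ungapped
offset (1 for a deterministic perfect complement, 0.25 for a uniform
PFM); information content is mean bits per column against a uniform
background; the combined confidence is
`c = (−log10(p) − 10)/10 + (s − 0.35) × 6.7` with retention at s ≥ 0.35,
IC ≥ 1.75 bits/bp and c ≥ 1. With foreground resampled from the
background pool, zero motifs pass retention across seven iterations
(tested across many seeds during development of the engine design).

## Family specificity

Seed families are defined by identical positions 2–8 computed from the
catalogue. Strict assignment re-runs detection with zero mismatches and
discards reads whose candidate set still spans more than one miRNA; the
strict hit set is a subset of the default set by construction. Pairwise
specificity folds each member's target regions (used verbatim) against
every member without seed forcing; one-tailed Welch t-tests ask whether
cognate duplexes are more stable, identical distributions report p = 0.5,
and mean cognate-versus-cross gaps > 6 kcal/mol are flagged as strong
specificity. Member-specific motifs run the motif engine at k ∈
{6, 8, 10, 12} against a pooled AGO-bound background and are displayed
reverse-complemented so they read along the miRNA, flagged when they map
to the divergent 3′ region (positions > 8).

## Perturbation response

Probe-level log2 fold-changes are collapsed per gene (genes with
sign-contradictory probes removed, remainder averaged; idempotent).
Site-class gene sets follow the mutually exclusive constructions
(canonical-only versus non-canonical-only at transcript level, sites seen
once versus multiple times, peak-supported versus chimera-only), with the
control always genes carrying only other-miRNA chimeras; "7-8mer seeds"
means {8mer, 7mer-m8, 7mer-A1}. Comparisons are two-sample KS tests
(verified against an R reference in the test suite). Binding-change CDFs
use pseudocounted normalized cluster counts (so zero-count clusters are
defined), filter at BC ≥ 4 and density ≥ 40, and test each site class
against the neither-seed-nor-chimera class.

## Synthetic experiments

The generator's defaults are the study conditions: 50,000 reads over 4
ligase-treated and 2 no-ligase samples; miR-first chimeras at 3% of
molecules in ligase samples (inside the observed 1.5–5% band) with a 10×
drop without ligase; miR-last at 1/14 of the miR-first rate,
ligase-independent; truncation mass 0.85/0.15 at 0/1 nt; a seed-class
mixture of 25/20/15/15% canonical 8mer/7mer-m8/7mer-A1/6mer, 10%
mismatch, 5% bulge and 10% seedless (3′-complementarity-only) sites; 1%
cross-species contamination; 20% PCR duplication; 18 miRNAs including two
3-member seed families sharing 10 nt; 120 genes with
5′UTR/CDS/intron/3′UTR structure on two chromosomes, sites placed 70% in
3′UTRs. Site sequences are written into the genome at known offsets
(2–20 nt) downstream of recorded junctions, flanked by guard bases so a
chance neighbouring base cannot upgrade the planted class (a 7mer-m8
followed by a random A would otherwise be a true 8mer 25% of the time).
The contaminant genome shares no exact 20-mer with the primary genome,
making the false-ligation estimate identifiable. Expression effects are
−0.5 (canonical) and −0.2 (non-canonical) log2 units with N(0, 0.25)
probe noise. Binding-mode archetypes (seed-only, seed + 3′ supplementary,
seed + long 3′, seedless-3′, bipartite, tripartite) are realized directly
in pairing-profile space with independent bit-flip noise for clustering
benchmarks.

What the generator does not emulate: real sequence composition (uniform
bases by default, with an AU-rich-3′UTR option), repeat structure and
multi-mapping ambiguity at realistic rates, quality-score variation,
ligation sequence biases, and isoform complexity. Passing generator-truth
tests therefore demonstrates correctness of the algorithms under the
stated statistical conditions, not performance on real libraries.

Truth evaluation is at the unique-molecule level, since PCR duplicates
collapse to a single representative read. The seed-class confusion
diagonal is computed over planted canonical classes; planted
mismatch/bulge sites are scored separately as variant-class recovery,
because random 75-nt regions carry accidental single-edit variant sites
of the short classes at a non-trivial floor.

## Problem sizes and defaults

Validation runs use the generator defaults above (50,000 reads for
detection; 3,000 profiles for clustering; 500 interactions for the
shuffled null; 100 regions per family member; 2,000 fragments for
false-ligation estimation; 200 simulations for the KS null), sizes chosen
so the whole suite and the reproduction script each complete in well
under a minute of compute apiece on one CPU while leaving binomial noise
small relative to the asserted margins.

## Interfaces

`detect`, `cluster` and `simulate` are shell subcommands because they
consume and produce files; the analysis layers (seed taxonomy, duplex
folding, clustering, motifs, family and perturbation statistics) are
library functions operating on in-memory tables, which is how they are
meant to be composed. All thresholds named above are keyword arguments
with the stated defaults; the energy table is a TSV data file.
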