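# Methods

This note documents the models and procedures implemented in `symbionet`,
the parameters that matter, the design choices made where the published
descriptions left the design open, and what the synthetic-data tests do and
do not demonstrate.

## Fragment-based gANI/AF

Genome average nucleotide identity between a query (bin or genome) and a
reference is usually computed from bidirectional best hits of predicted
genes. `symbionet` instead uses a fragment-based formulation: the query is
cut into consecutive windows of `fragment_bp` (default 1000 bp, floor
200 bp; trailing remainders under 100 bp are skipped as too noisy to
score), and each window is aligned to the reference on both strands with
semiglobal (infix) edit-distance alignment. Window identity is
`1 − edit_distance / window_length`; a window maps when identity reaches
`min_fragment_identity` (default 0.70). Because infix alignment always
places the entire window, the identity floor alone decides mapping; a
separate coverage gate would be redundant. Then

    AF   = mapped window bp / total query bp
    gANI = Σ identityᵢ · lenᵢ / Σ lenᵢ over mapped windows.

The fragment formulation needs no gene calls, which matters for bins with
poor annotation, and on substitution-only data it converges to the
analytic value 1 − d (the acceptance run measures |gANI − (1 − d)| ≤
2×10⁻⁴ at d ∈ {0, 0.02, 0.05, 0.10} on 100 kb genomes). With indels or
repeat-rich references the two formulations can differ; this implementation
makes no claim of numerical equality with gene-based gANI on real genomes.

Assignment cutoffs are strict inequalities (AF > 0.5 and gANI > 0.9),
matching the published wording; conspecificity is gANI ≥ 0.95. Ties in
assignment break by larger AF, then lexicographic reference id, so outputs
are deterministic. Aggregate (species-level) gANI is the length-weighted
mean over member bins.

The bacterial-bin classifier requires coding density > 0.5 and a bacterial
fraction ≥ 0.60 among *classified* genes; genes the taxonomy oracle left
unassigned are excluded from the denominator by default
(`count_unassigned=True` includes them). Taxonomy labels are injected per
gene rather than computed, so any external classifier can stand behind the
interface.

## Read mapping and composition

The mapping contract is explicit rather than delegated to an external
mapper: a read maps to a reference iff its best alignment (both strands,
all contigs, semiglobal) contains an exact run ≥ `min_exact_seed` (22 bp),
≤ `max_subs` substitutions (15) and ≤ `max_indel` indel bp (80). These
values translate a common short-read competitive-mapping configuration into
testable semantics; the exact-seed term is our reading of a minimum
contiguous exact k-mer filter. Each read is assigned uniquely to the
reference with the fewest mismatches (ties: fewest indel bp, then
lexicographic). Composition is reads per species / total reads × 100;
species under `minor_floor_pct` (default 0.5%) pool into a "minor"
category, and percentages plus unmapped always total 100.

## Marker-window strain profiling

The marker is tiled with non-overlapping windows of `window_bp` (default
50; the last window may be short). A read contributes a variant to a window
only when its alignment fully covers the window — partial overlaps are
skipped per window, so ragged read edges cannot create composite variants.
Reads whose best placement on the marker requires indels are skipped
entirely; the substitution-only simulator never produces them, and on real
data indel reads near a single-copy marker are rare enough to ignore for
SNP counting. Variants with fewer than `min_support` reads (default 2) are
dropped as sequencing noise.

`min_strains` is the maximum number of supported variants in any window: a
lower bound on the true strain count, tight exactly when some window
contains sites discriminating every pair of strains and coverage suffices
for `min_support`. The mixture estimator pools rank-ordered variant
fractions across polymorphic windows and reports the per-rank medians,
normalised to sum to 1. It is a summary statistic of the window profile,
not a haplotype-phasing model; strains that are identical over the marker
are invisible to it by construction.

## BGC networking into GCFs

Protein-protein comparisons use local alignment (BLOSUM62, gap open −11,
extend −1). Identity is computed over aligned columns, coverage as the
aligned span over each sequence's length. A fast edit-distance prescreen
(shorter protein infix-aligned into the longer; reject above 75% of the
shorter length in edits) skips the scored alignment for clearly unrelated
pairs, and results are memoised, which keeps all-versus-all comparisons of
tens of clusters in seconds. Two threshold tiers exist: loose (identity
≥ 30%, both coverages ≥ 25%) approximating a default homology search, and
strict (≥ 60% identity, ≥ 80% coverage of both) for the refinement step.

A directional cluster hit from query to subject requires ≥ `min_shared`
(default 3) query genes with loose-tier subject homologs. Its score is
`shared · (1 + synteny)` where synteny is the longest co-linear run of hits
divided by the shared count — a monotone stand-in for multi-gene search
scores (more homologs and conserved order score higher); an adapter could
substitute real tool output without touching the network logic.

Edges: bidirectional hits are accepted outright (weight = mean of the two
scores). For single-directional hits the truncated member is the cluster
with fewer genes — under metagenome fragmentation the fragment is the
shorter one — and the hit is retained iff its strict-tier gene hits `s`
satisfy `s ≥ max(n − 2, 1)` with `n` its gene count; the floor of 1 avoids
evidence-free edges when n ≤ 2. GCFs are connected components, numbered by
descending size then lexicographic smallest member. Component assignment is
the reproducible formalisation of what is otherwise a manual network-viewer
grouping; edge weights and types are exported (GraphML/SIF) for review.

## Occurrence and the collapse estimator

Core proteins of a GCF are the core-flagged genes of its longest member
(ties prefer larger span, then isolate source, then id); without flags, the
longest member's genes with strict homologs in at least half the members.
The translated search aligns each protein against all six reading frames of
each contig; hits need > 50% query coverage and > 90% identity (strict
inequalities), and aligned spans containing a stop codon are rejected.
Hits on one contig within 10 kb cluster into one locus.

Occurrence counts are distinct loci per (GCF, specimen), combining network
membership of the specimen's own BGCs with translated-search loci;
overlapping intervals on the same contig deduplicate, so double evidence
for one locus counts once. The per-specimen table divides species totals by
specimen number: 1 means present in every specimen, < 1 a fraction of
specimens, > 1 multiple subtype loci.

Collapse: each metagenome BGC is assigned to its best-scoring reference
cluster, and within one (specimen, reference) group the unique count is the
maximum overlap depth of the fragments' reference-gene-index intervals —
complementary fragments (disjoint ranges) merge as pieces of one split
cluster, while overlapping ranges (full-length duplicates) stay distinct.
This greedy interval-partitioning count is exactly the minimum number of
co-resident clusters consistent with the fragments. The inflation factor is
matched fragments / unique clusters, and the unique-BGC estimate for a
whole dataset is `n_total / inflation` — the "roughly double" rule observed
in real gill metagenomes generalised to the measured ratio. The estimator
assumes the matched subset's fragmentation rate is representative of the
unmatched remainder.

## Synthetic data: what it does and does not emulate

Generators are substitution-only (genomes, proteins, read errors), with
uniform random placement and exact counts (`round(d · L)` changes), so
expected identities are analytically 1 − d and every acceptance check has a
closed form. Indels, coverage bias, chimeras, paired ends and quality
models are deliberately out of scope. BGC truncation is terminal-contiguous
(a prefix or suffix of the gene order), mimicking contig-edge
fragmentation. Bins are verbatim subsequences of source strains with known
provenance; marker mixtures plant SNP haplotypes at known proportions.

Consequently, passing tests demonstrate correctness of the inference logic
under the stated noise model — they do not demonstrate robustness to indel
divergence, horizontal transfer within BGCs, or assembly chimerism, and the
published counts from real specimens (which depend on external archives and
specific annotation-tool versions) are not reproduced here.

Problem sizes in the test and acceptance runs (100 kb genomes, 20 bins,
10,000 reads, 8 planted families, 75 fragments) were chosen as the smallest
sizes at which the binomial/ARI acceptance margins are comfortably
non-degenerate; all generators scale to larger inputs unchanged.

## Determinism

Every generator takes an integer seed and uses a single `numpy` generator
per invocation; every pipeline tie-break (assignment, read mapping, GCF
numbering) is total-ordered. Two runs with the same seed are byte-identical
across all stages, which the test suite asserts by serialising every
stage's output.
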