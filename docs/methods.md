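# Methods

## Overview

karyofuse infers chromosome fusion-with-mixing (FWM) from pairwise
gene-order data. The pipeline is: mutual-best ortholog placement →
`.psynt` synteny table → scaffold filtering → Fisher-exact homology
graph → chromosome fates and fused-pair extraction → normalized
turbulence per fused pair. A simulator generates inputs with known
event histories so that every stage can be validated against ground
truth.

## Coordinates, formats, and the `.psynt` dialect

All intervals are 0-based half-open internally; GFF (1-based closed)
is converted once at the parsing boundary, BED is taken as-is. Gene
position for ordering is the interval midpoint, strand ignored: every
downstream statistic uses ordinal gene rank, not physical distance, so
genomes of very different physical size (e.g. a 14 Gb draft versus a
0.7 Gb chromosome-level assembly) compare cleanly.

`.psynt` is fixed here as a 7-column TSV with a `#` header
(`ortholog, scaffold_a, pos_a, rank_a, scaffold_b, pos_b, rank_b`);
ranks are dense 0..k−1 per scaffold after sorting by position. Reading
and writing round-trip exactly; violations (column count, duplicate
ortholog ids, non-dense ranks) are rejected with line numbers.

## Mutual-best orthologs

A single reference peptide set is mapped independently to both genomes
(miniprot-style GFF is parsed with gffutils; the alignment score comes
from GFF column 6 or a named attribute). Per peptide and genome the
highest-scoring placement is kept iff its identity ≥ `min_identity`
(default 0.0) and the runner-up scores at most `score_ratio` (default
0.9) of it; exact ties are ambiguous and drop the peptide. An ortholog
pair is the (best-in-A, best-in-B) placement of one peptide. This is a
deterministic, auditable realization of "mutual best" that needs only
per-genome mapping output; it trades recall for one-to-one confidence.
Both guards are exposed on the CLI.

Scaffold filtering keeps only scaffolds with ≥ 15 orthologs (default).
Because removing rows on one side can starve scaffolds on the other,
the filter iterates to a fixed point, which also makes it idempotent.

## Homology testing

For the shared-ortholog count matrix C (scaffolds_a × scaffolds_b,
total N), each cell is tested one-sided (greater) with Fisher's exact
test: p = P(X ≥ C[i,j]) for X hypergeometric with population N,
successes rowᵢ, draws colⱼ — vectorized via `scipy.stats.hypergeom`.
One-sided because every hypothesis here is an enrichment hypothesis.
Bonferroni correction uses m = number of scaffold pairs in the
filtered matrix. Edges with adjusted p < α (default 0.05) form the
bipartite association graph.

Chromosome fates read off the graph: `unplaced` (degree 0),
`one_to_one` (single, exclusive partner), `fused` (some partner is
shared with another reference chromosome), `split` (≥ 2 partners, all
exclusive), `complex` (otherwise). Fused pairs are all reference pairs
sharing a derived partner. Fates are invariant to scaffold relabeling.

The contig-level co-occurrence FWM test classifies each query contig by
presence (≥ 1 ortholog by default) of each of two reference
chromosomes and applies the same one-sided Fisher test to the 2×2
presence table over contigs. The all-pairs scan is uncorrected at 0.05
by default — presence-based co-occurrence over contiguous fragments is
already conservative under the null (unrelated chromosomes' genes
virtually never share a contig) — with Bonferroni available behind a
flag. This contig-level construction (rather than a gene-level one) is
this package's normative choice for fragmented assemblies.

## Turbulence and its normalization

For the label sequence x (ancestral labels along a derived scaffold,
optionally restricted to a candidate fused pair):

- DSS: run-length encoding into d spells with durations t₁…t_d.
- φ: distinct subsequences of the DSS sequence via the standard DP
  φᵢ = 2φᵢ₋₁ − φⱼ₋₁ (j the symbol's previous occurrence), in exact
  integer arithmetic; log₂ is taken on the exact integer at the end,
  so there is no precision loss even at n = 10⁴ (φ has thousands of
  bits).
- s² is the population variance (divide by d) of durations;
  s²ₘₐₓ = (d−1)(1−t̄)², t̄ = n/d.
- T = log₂(φ · (s²ₘₐₓ+1)/(s²+1)).

Normalization is min–max with explicit endpoints: T_min is the
turbulence of the single-spell sequence of length n (identically 1)
and T_max that of the strictly alternating sequence over the observed
alphabet. Both endpoints are achieved, the result is clipped into
[0, 1], and the degenerate case T_max = T_min yields 0. The
normalization is pluggable (`NORMALIZATIONS` registry /
`normalization=` argument) because sequence-analysis packages differ
in their normalization conventions and the equivalence of this rule
with any particular external implementation is not guaranteed;
consequently, reproduction of absolute turbulence values computed by
other software is contingent on that equivalence, while comparisons
*within* one convention (sharp vs mixed, quartile classification) are
robust.

Quartiles over fused-pair values use linear interpolation between
order statistics (quantile q at position 1+(k−1)q, numpy's default);
a fused pair is classified `sharp` if its value is strictly below Q1,
`mixed` otherwise (Q1 itself counts as mixed).

Calibration points (computed, not assumed): a sharp 100+100 fusion
scores T = log₂(4·9802), T_norm ≈ 0.103; a fully interleaved 100+100
fusion averages ≈ 0.54; real-data sharp translocations reported in the
literature sit near 0.08, inside the same regime as our sharp
calibration.

**Known non-monotonicity.** Mean T_norm is *not* monotone from m = 0
(sharp) through light mixing: a balanced two-spell fusion earns a large
(s²ₘₐₓ+1)/(s²+1) factor (≈ 9802 for 100+100) which light mixing
destroys before the φ term grows enough to compensate — measured means
are 0.103 (m = 0), 0.074 (m = 0.25), 0.097 (m = 0.5), 0.540 (m = 1).
Monotonicity holds across positive intensities; the sharp/mixed
dichotomy the pipeline relies on (m = 0 vs m = 1) is cleanly separated
in every tested replicate.

## Simulator

`make_ancestor(k=46, genes_per_chrom=100)` builds the shared ancestor;
defaults mirror a squid-like karyotype of ~46 chromosomes with enough
genes per chromosome (100) that per-pair tests are well powered while
a full pipeline replicate stays fast. Events:

- `FUSE`: concatenation, sharp boundary (exactly one label
  change-point).
- `FUSE_MIX(m)`: concatenation then mixing; m = 1 draws a uniform
  permutation of the merged order, 0 < m < 1 performs ⌈m·n⌉ random
  adjacent transpositions per gene (m·n² total swaps), a monotone dial
  from sharp to fully interleaved. At m = 1 the expected number of
  label change-points is 2·n_A·n_B/(n_A+n_B) (runs of a random binary
  arrangement), verified by simulation.
- `FISSION` (given or random index), `TRANSLOCATE` (contiguous
  segment, given or random span and insertion point),
  `INTRA_SHUFFLE`, `LOSS` (independent per-gene deletion).

Gene counts are conserved by everything except LOSS; ancestral labels
are immutable; mixing is forward-only (no event restores a pre-mixing
order), reflecting FWM irreversibility. A single generator seeded once
per `evolve` run drives all stochastic choices in event order, so runs
are bit-reproducible.

`emit_observed` bridges simulator and pipeline: each shared gene is
retained independently with probability `retention` (default study
condition 0.9, modelling incomplete orthology recovery), and positions
are synthesized as rank × 10 kb — only order matters downstream.
`fragment_genome` cuts each scaffold into consecutive blocks with
sizes drawn with replacement from an empirical genes-per-contig
profile (last block truncated), matching a draft assembly
distributionally rather than contig-by-contig; fragment ids sort back
to the parent order, so fragmentation is exactly invertible. The
fragmentation control uses a profile with mean 20 genes/contig
(1 + Poisson(19)), a draft-like contiguity under which the ≥ 15
ortholog filter still retains most contigs.

What the simulator does *not* emulate: nucleotide sequences, repeat
content, paralogy/whole-genome duplication, mapping noise correlated
with position, assembly chimerism, and unequal gene density. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under clean one-to-one orthology, not robustness to every
real-data artifact.

## Problem sizes and numerical choices

Validation experiments use a 46-chromosome × 100-gene ancestor
(4 600 orthologs), 10 replicate seeds per experiment, and 1 000
replicates for the null calibration — sizes at which every expected
effect is decisively measurable. Ward clustering of shared-ortholog
profiles uses `scipy.cluster.hierarchy.linkage(method="ward")`
(ward.D2 semantics: squared update on unsquared Euclidean distances)
with inputs pre-sorted by scaffold id so merge ties resolve
deterministically. Dotplots place one marker per ortholog at
cumulative rank coordinates; SVG output is byte-deterministic (fixed
hash salt, no timestamp) so renderings are testable.

## Limitations

- The homology test treats ortholog placements as exchangeable; local
  gene-order autocorrelation in real genomes makes contig-level
  co-occurrence conservative but can make gene-level counts slightly
  anti-conservative at very small N.
- Fate calling is pairwise; no parsimony synthesis across > 2 genomes.
- Absolute turbulence values depend on the normalization convention
  (see above); only within-convention comparisons are interpretable.
- The mutual-best construction depends on a single reference peptide
  set; anchoring on a different reference can change the recovered
  ortholog set (both anchors are supported, never merged).
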