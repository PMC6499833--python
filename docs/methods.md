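# Methods

`titrseq` analyses dose-titration ("graded inhibition") transcriptomics:
a cell line is exposed to a control condition plus a ladder of inhibitor
concentrations, the transcriptome is quantified at each dose, and the
questions of interest are (i) which genes, transcript isoforms and
splice events respond *monotonically* to increasing inhibition, (ii) how
the responding splice events are structured (type composition,
reading-frame consequences, terminal-exon choice), (iii) which RNA-binding
proteins' motifs are enriched around the responding events, and (iv)
which biological processes the responding genes concentrate in.

## Dose-response clustering

**Normalization.** Expression tables are FPKM-scale. Dose columns are
made comparable by upper-quartile scaling: each column is multiplied by
`ref / UQ(column)`, where `UQ` is the 75th percentile of the column's
positive values and `ref` is the geometric mean of all columns' UQs. The
geometric-mean reference is symmetric in the columns and scale-free;
zeros are preserved. Scaling any dose column by a constant therefore
leaves everything downstream unchanged (tested as an invariance).

**Abundance filter.** Features with mean FPKM < 1 or median 0 are
removed, as are features whose max is not at least 1.5× their min across
doses — a minimum-change requirement that discards variation attributable
to sampling noise.

**NMD inclusion ratios.** For transcripts flagged with an NMD biotype,
the inclusion level is Ψ = isoform FPKM / gene FPKM per dose. Isoforms
with mean Ψ ≤ 0.05 or median Ψ ≤ 0.001 are dropped; ratios above 1
(isoform quantified above its gene, which happens with independent
quantification error) are flagged and retained rather than rejected.
Isoforms whose gene has zero FPKM at any dose are dropped with a log
entry.

**Network and clustering.** Co-response is measured by a signed weighted
correlation network: adjacency `a_ij = ((1 + cor(x_i, x_j))/2)^β`, with
β = 10 for FPKM profiles and β = 6 for Ψ/inclusion profiles. The signed
transform keeps anti-correlated profiles apart (cor = −1 → a = 0).
Pearson correlation is computed over the ≤ 7 dose points; zero-variance
features are dropped with a log entry. The adjacency is converted to the
topological overlap measure

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

which rewards shared neighbourhoods and is robust to single spurious
correlations. Features are clustered by average-linkage hierarchical
clustering on 1 − TOM with a fixed cut height (default 0.9); clusters
smaller than `min_module_size` (default 30, usable down to 5 for desk
tests) are pooled as "unassigned". A fixed cut replaces dynamic tree
cutting to keep the procedure deterministic and dependency-free. The
default height was set from the geometry of the dissimilarity: with
5-dose profiles at β = 10, profiles sharing a direction sit at 1 − TOM
up to ≈ 0.6 while opposite or unrelated profiles sit at ≈ 1.0, so any
cut in (0.6, 1.0) separates the structure and 0.9 leaves headroom for
noise; a low cut (e.g. 0.25) fragments genuine modules.

**Consensus and monotonicity.** A cluster's consensus is the per-dose
mean of its members' min-max-normalized profiles; normalizing first
prevents high-abundance members dominating. The consensus is labelled
*increasing* when Spearman ρ against dose rank is ≥ 0.9 (inclusive, with
a 1e-9 epsilon guarding the float comparison — a single adjacent rank
inversion over 5 doses gives ρ of exactly 0.9) **and** no consecutive
step decreases by more than 5% of the profile range; *decreasing* is
symmetric. Both thresholds are configurable; the rule is an operational
stand-in for what is usually a visual call on consensus curves.

**Cross-condition overlap.** Monotone feature/event id sets from several
conditions are summarized as exclusive (UpSet-style) intersection bins,
plus the fraction of the union shared by ≥ 2 conditions, and a pairwise
direction-concordance table (fraction of shared ids with the same
label).

## Splice-event statistics

Event calls arrive from two caller families with different confidence
semantics: *misolike* records carry a Bayes factor and are kept when
|ΔΨ| ≥ 0.1 and BF ≥ 10; *vastlike* records carry the minimum |ΔΨ| at
0.95 confidence (MV) and are kept when MV ≥ 0.1. Merging deduplicates by
the exact (type, chromosome, strand, alternative-segment interval) key —
deterministic, at the cost of missing near-identical events with
slightly different boundaries; on a collision the misolike Ψ values are
kept and provenance lists both callers.

An event's alternative segment (skipped exon or retained intron) causes
a frameshift when its length is not a multiple of 3. Frameshift
over-representation in a monotone set against the background of all
annotated events of the same type outside the set is tested with a
one-tailed (enrichment) Fisher's exact test, computed as the
hypergeometric upper tail. Alternative-last-exon events are classified
proximal/distal by whether the selected last exon is the 5′-most
candidate in transcript orientation, and the proximal bias between
increasing and decreasing sets is a 2×2 chi-square without continuity
correction (a warning, not an error, is raised when an expected cell is
below 1). Detection rates per event type are reported as detected /
annotated counts.

## RBP motif enrichment

**Regions.** A skipped-exon event is decomposed into seven
transcript-oriented regions: the 5′ exon, the skipped exon, the 3′ exon,
and 300-nt windows at the start and end of each flanking intron. A
retained-intron event gives four regions: both exons and the intron's
start/end windows. Introns shorter than 600 nt have their windows
truncated at the midpoint so they never overlap. Minus-strand events are
reverse-complemented; only the transcript's sense strand is scanned,
because the binding substrate is single-stranded RNA.

**Scanning.** Background A/C/G/U frequencies are estimated empirically
with add-one smoothing. Each position probability matrix becomes a
log-odds scanner, `w[i,b] = log2((p[i,b] + ε)/q_b)` with pseudocount
ε = 0.001 (CIS-BP matrices contain zeros). The motif's maximum
achievable window score is Σᵢ maxᵦ w[i,b] — the only sequence-independent
reading under which "80% of the maximum" is a fixed per-motif threshold
(the alternative, max observed score over scanned sequences, is
supported by rescoring). A window is a hit when its score is strictly
above 0.8 × max; overlapping hits all count. Motifs sharing an RBP are
grouped and their hits merged as distinct (position, motif) pairs.

**Testing.** Positive events are compared with 10 background events
each, drawn from the same quantile length bin (10 bins by default)
without replacement, falling back to replacement only when a bin is
exhausted (logged). Hit counts are divided by region length, compared
with a two-sided Mann–Whitney U test (exact enumeration when both
samples are ≤ 20 and tie-free, tie-corrected normal approximation
otherwise), and BH-corrected across the full (group × region ×
direction) table of a run. An enrichment/depletion call additionally
requires the positive/background mean-rate ratio to be at least 25%
above or below 1. Positional densities report, per offset in ±200 nt
around a skipped-exon junction, the fraction of events with a merged
group hit starting there.

## Gene-set enrichment

Over-representation of an identified gene list in each gene set is the
hypergeometric upper tail P(X ≥ k) with X ~ Hypergeom(N, K, n), BH
corrected across the query. The universe defaults to all features
surviving the abundance filter for the condition (the choice is
configurable). Sets passing q < 0.01 and p < 0.005 become nodes of an
enrichment map; edges join pairs with member Jaccard ≥ 0.25 and clusters
are connected components with numeric labels. The signed score
(k/K)/(n/N) is negated for decreasing-direction queries so both
directions share one axis.

## Synthetic data generator

The generator emulates the study's data structure so every stage has a
parameter-recovery surface:

* **Doses:** control plus {0.5, 2, 5, 10} μM by default (5 levels).
* **Expression:** planted monotone features follow a geometric ramp with
  max/min exactly `effect_size` (default 2); nulls are flat. Noise is
  multiplicative log-normal (σ = 0.1 in log space by default) so
  non-negativity is structural. Labels are shuffled across feature ids.
* **Isoforms:** each gene splits into 1–3 isoforms whose noise-free
  profiles sum exactly to the gene profile; a designated subset of
  NMD-flagged isoforms has inclusion ratio rising geometrically with
  dose.
* **Events:** one synthetic chromosome, events laid out with 1-kb
  spacers, exons 150 nt, introns 800 nt; alternative-segment lengths are
  drawn so the out-of-frame fraction is 0.8 among planted-monotone
  events and 2/3 among background. Ψ profiles are monotone/null with
  logit-space Gaussian noise (stays in (0,1)). Caller confidence is
  drawn above threshold for planted events and mostly below for nulls.
* **Sequences:** i.i.d. background at configurable base frequencies;
  motif instances are *sampled from the PWM* (per-position categorical
  draw, not consensus-only) and planted as Poisson(density ×
  length/1000) in each scannable region — the designated region of
  positive events at 6 instances/kb, everywhere else at 2/kb (a 3×
  ratio). The absolute scale gives ≈ 1.8 planted instances per 300-nt
  positive window; since a PWM-sampled instance of a sharp 7-mer passes
  the 80%-of-max threshold only ≈ 32% of the time, this leaves ≈ 0.6
  scannable planted hits per window, enough for the planted group to be
  the unambiguous top hit after BH in every tested seed. At lower
  absolute densities the same ratio is detected at raw p < 0.01 but
  does not reliably survive multiplicity correction.

What the generator does **not** emulate: read-level sampling (no
replicate structure or FPKM–variance coupling), genuinely shared splice
sites between events, correlated noise across features, realistic genome
composition, or motif co-occurrence. Passing recovery tests therefore
demonstrate correctness of the computational pipeline under its stated
model, not performance on real libraries.

## Problem sizes and numerics

The test and acceptance runs use 200-feature expression matrices
(10 seeds), 500-event SE-only bundles with ~100 positives (10 seeds),
and oracle sweeps over all 2×2 tables with total ≤ 40, universes to
N = 60, Mann–Whitney samples to 7+7 and TOM matrices to 8×8 — sizes at
which the independent enumeration oracles are exact and fast. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; reruns of the pipeline with the same config
and seed are byte-identical (no timestamps in output headers). Degenerate
inputs are handled explicitly: all-zero dose columns are errors,
zero-variance profiles are dropped and logged, empty contingency margins
return p = 1 with a warning, and regions shorter than a motif yield zero
hits.
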