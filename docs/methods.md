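# Methods

## Scope and model

`pgmine` treats pathway discovery in assembled transcriptomes as a
deterministic annotation-mining problem. The unit of input is a
*bundle*: one transcriptome's predicted peptides, its Swiss-Prot
annotation table, a per-contig read-count table and metadata (species,
genus, strain, growth conditions, an MMETSP-style accession code). The
pipeline makes four passes over a set of bundles:

1. **mining** — substring query of annotation descriptions, then
   canonicalization against a controlled enzyme vocabulary;
2. **clustering** — greedy collapse of redundant transcripts per
   (species, function) at an amino-acid identity threshold;
3. **quantification** — per-transcript FPKM, summed per
   (transcriptome, function);
4. **summarization** — presence matrices, occurrence counts, censuses,
   assembly statistics and figures.

No stage uses randomness, so a rerun on the same inputs reproduces all
tabular outputs byte-identically.

## Vocabulary and canonicalization

The built-in vocabulary holds the nine prostaglandin-metabolism
functions (six synthesis: COX2, HPGDS, PTGES2, PGE2-9-OR, PTGFS1,
PTGFS2; three catabolism: 15-PGDH, PTGR1, PTGR2), each with the
Swiss-Prot protein names and common abbreviations under which hits for
that function appear. Canonicalization tries synonyms longest-first
with case-insensitive substring containment, so a full protein name
always wins over an abbreviation embedded in a longer, different name.
A synonym claimed by two codes is rejected at load time.

Matching operates on the description field only. A term-matching
description that canonicalizes to no entry is reported as *unmapped*:
this is the auditable hedge against pathway-adjacent annotations
(transporters, receptors) inflating the result, and the synthetic
near-miss decoys exercise it.

Design choice: a transcript annotated with two *different* pathway
functions keeps both assignments; duplicates of the same
(transcript, function) pair collapse to one, retaining the
lexicographically smallest matching description so the output is
invariant under annotation-row order.

## Identity metric and clustering

Identity between two peptides is the number of matched residues in an
optimal global alignment with match 1, mismatch 0 and zero gap penalty
— equivalently the longest-common-subsequence length — divided by the
length of the **shorter** sequence (so perfect fragments score 1.0
against their parent). This is computed with Biopython's
`PairwiseAligner`; the scoring scheme makes the optimal score exactly
the LCS length, so the metric is well defined without any gap-parameter
nuance. The shorter-sequence denominator follows the common
short-vs-long convention of greedy clusterers and is stated explicitly
because it changes cluster counts.

Greedy clustering visits sequences in length-descending order (ties
broken by ascending id — a deterministic stand-in for the otherwise
irreproducible input-order dependence of greedy clusterers); each
sequence joins the **first** existing cluster whose representative it
matches at ≥ threshold, else founds a new cluster. The default
threshold is 0.90 amino-acid identity, the customary default for
redundancy removal; it is configurable everywhere.

A residue-multiset bound (shared residue counts / shorter length) is an
exact upper bound on LCS identity and is used to skip hopeless pairs;
because the bound is never optimistic by less than the true value, the
prefilter provably cannot change results relative to
`brute_force_cluster`, the exhaustive all-pairs oracle with the same
contract (limited to ≤ 50 sequences). Oracle equivalence over random
mixed instances is part of the test suite and the acceptance script.

Clustering is run independently per (species, function) group, pooling
a species' replicate transcriptomes, which matches how redundancy
removal is done in per-species surveys; a pooled all-species run plus
`cross_species_purity` is available to check that clusters do not mix
species or functions.

## Expression

FPKM is evaluated exactly as

    FPKM = mapped_read_pairs / (length_bp / 1000) / (total_read_pairs / 1e6)

with division-by-zero inputs rejected. Read counts are treated as
fragment (pair) counts throughout; single-end data changes the label,
not the arithmetic.

Per (transcriptome, function) the FPKM values of a contributing set are
summed. Two modes are implemented because either is defensible:

- `heads` (default): one transcript per gene — for each cluster and
  each transcriptome, that transcriptome's longest member (ties by
  ascending id). The *local-head* rule is needed because clustering
  pools replicates: the global cluster head lives in one replicate
  only, while expression is a per-transcriptome quantity, and every
  transcriptome in which a function is annotated must receive a record.
- `all`: every assigned transcript contributes.

Absence is meaningful: a function with no assigned transcript in a
transcriptome produces **no** record, matrices encode it as a missing
cell (NaN in memory, empty field in TSV), and heatmaps render missing
cells in a reserved grey distinct from the colormap. Heatmaps use raw
FPKM by default with an optional `log10(x+1)` transform.

## Assembly statistics

N50 is the classical definition: sort contig lengths descending,
accumulate, and report the length at which the cumulative sum first
reaches half the total assembly length. It is validated against an
independent cumulative-walk oracle and is permutation-invariant by
construction.

## Synthetic data

The generator emulates the bundle file set with fully known truth. Per
species it plants one gene per chosen function: a uniformly random
peptide backbone (default 300 aa; only identity structure matters
downstream, so no compositional realism is attempted) plus
`copies_per_gene − 1` copies mutated by substitution only —
`round((1 − identity) · length)` positions changed to different
residues, no indels — at `copy_identity` (default 0.95). All replicate
transcriptomes of a species carry the same gene copies under their own
transcript ids, so per-species clustering sees one copy group per gene.
Decoys (default 50 per transcriptome) are random peptides with
non-pathway annotations; a `decoy_annotation_rate` fraction (default
0.1) instead carries near-miss descriptions that contain the query term
but canonicalize to nothing. Near-miss decoys are on by default because
they are what distinguishes vocabulary-gated mining from bare keyword
search.

Counts are gamma-mixed Poisson: mean *m*, dispersion φ, variance
m + φ·m² (gamma shape 1/φ). Defaults m = 200 mapped pairs per planted
copy, 50 per decoy, φ = 0.5 — overdispersed enough that replicate
heatmap columns visibly disagree, as replicate transcriptomes of the
same strain tend to. φ = 0 selects a degenerate deterministic model
(counts = round(m)) for replicate-identity checks. The library total is
held fixed at `total_read_pairs_mean` (default 10⁶) rather than drawn,
so the analytic expectation of a head's FPKM,
m / (L/1000) / (T/10⁶), is exact and recovery can be tested against it
at ±3 standard errors.

Default study conditions: 3 species x 2 replicates, 4 functions per
species (chosen uniformly per species from the nine), 3 copies per gene
at 0.95 identity, 50 decoys. With copy identity at or above the 0.90
clustering threshold and positive expression, the pipeline recovers the
planted presence matrices exactly and each copy group collapses to one
cluster; this is asserted over 20 seeds.

What the generator does **not** emulate: nucleotide-level reads,
sequencing error, assembly artefacts, chimeric transcripts, paralog
families at intermediate identity, or annotation error beyond the
near-miss decoys. Passing tests therefore demonstrate correctness of
the mining/clustering/summation logic under controlled conditions, not
robustness to real annotation noise.

## Packaged survey tables

Three small TSVs transcribed from the published MMETSP dinoflagellate
survey make the summarization layer testable against real numbers: the
42-transcriptome growth-condition table (15 genera, 19 species — the
basionym pair *G. foliaceum* / *K. foliaceum* is kept as two species,
as the survey's tables do), the per-transcriptome assembly statistics
(one transcriptome has no reported values and loads as missing), and
the 14-species presence matrix. The survey's per-function SP/CD-Hit
cluster-count table is *not* transcribed: its merged-cell rendering is
ambiguous. Likewise the survey's pooled cluster total and its absolute
FPKM values require the original MMETSP sequences and are out of scope
here.

## Numerical and degenerate-input choices

- Identity ratios are exact integer ratios in double precision;
  threshold comparison is `>=`.
- FPKM sums use compensated summation (`math.fsum`).
- Empty assignment sets produce empty (but well-formed, fully-labelled)
  matrices and a successful pipeline run.
- Presence-matrix rows with no true cell are dropped; columns are
  always the nine vocabulary codes in fixed order.
- An empty assembly, an empty sequence, a non-positive threshold, a
  planted function outside the vocabulary, duplicate transcript ids or
  duplicate accession codes are all rejected with explicit errors.
- Figures are written with fixed PNG metadata so identical inputs give
  byte-identical images.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen
so the whole suite completes in well under a minute: 200 random
clustering instances of ≤ 30 sequences against the brute-force oracle,
20 end-to-end simulation seeds at the default conditions, and 200
simulated replicates for the expression-recovery check.

## Known limitations

- Keyword mining inherits the annotation table's quality; functions
  mis-annotated upstream are invisible to it.
- The LCS-based identity is more permissive than an edit-distance
  identity for rearranged sequences; at the thresholds used (≥ 0.7) the
  difference does not affect copy-group recovery, but the metric is not
  a substitute for alignment-quality inspection at low identity.
- Greedy clustering is order-dependent by nature; the deterministic
  visiting order makes results reproducible, not order-free.
- Cluster counts depend on the identity threshold; no attempt is made
  to pick the threshold from data.
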