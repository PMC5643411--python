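# Methods

This note documents the models, conventions and numerical choices behind
`umitcr`, in the order data flows through the pipeline.

## Amplicon model and coordinates

All coordinates are 0-based, half-open.  The library architecture assumed
throughout (and emulated by the simulator) is:

* **R2** begins with the ligation oligonucleotide: an 8-base spacer, six
  random bases, a second 8-base spacer, six more random bases.  The first
  30 bases of R2 therefore contain the complete 12-nt UMI; positions are
  fixed constants in `umitcr.layout`.  The spacers prevent hairpin
  formation in the UMI and act as a ligation fingerprint.
* **R1** begins with 6 random bases (cluster-diversity hexamer), the 6-base
  within-R1 sample index, a constant-region stub, then the rearranged
  V(D)J sequence read in V→J orientation.
* **I1** is the 6-base Illumina index read.

The spacer sequences in `layout` are fixed synthetic 8-mers; real protocols
supply their own via the `spacers` arguments.  The two bases of the 30-base
window beyond the second UMI slot are downstream sequence and are carried
but not interpreted.

## Demultiplexing

A composite read is `umi_region(30) ∥ I1 hexamer ∥ R1 hexamer ∥ R1`.
Records with R2 shorter than 30 nt or R1 shorter than 12 nt are dropped and
counted.  A read is assigned to a sample only when **exactly one** sheet
row matches both indices within the mismatch tolerance (0 or 1, default 1);
if several rows match — even when one of them matches exactly — the read is
routed to `undetermined`.  This is deliberately conservative: index sets
whose pairwise distance does not exceed twice the tolerance cannot be
demultiplexed reliably, and silently preferring the closer row would hide
that design flaw.  Index qualities are ignored for matching (an explicit
simplification).  Per-sample output prepends the 30-base UMI region to the
full R1; the index hexamers are consumed at this stage.

## Tag search and the five-part identifier

V and J genes are recognized by gene-specific tags (≥16 nt; pairwise
Hamming distance ≥2 within a segment class, enforced at reference load).
Single-mismatch search is implemented by expanding every tag to its 3L
Hamming-1 variants and compiling the expansion into an Aho–Corasick
automaton converted to a dense DFA — one table lookup per base.  A variant
owned exactly by one tag and at one mismatch by another belongs to the
exact owner; a variant owned at one mismatch by two tags (possible when
tags sit at distance exactly 2) keeps both owners, and such a hit surfaces
as a multiple-gene ambiguity.

A read is assigned when it has tag hits for exactly one V gene and exactly
one J gene with the V hit upstream; all other configurations are no-calls
with categorized reasons (no V, no J, multiple V, multiple J, order
violation, negative insert).  Multiple hits of the *same* gene keep the
leftmost V and the rightmost J hit compatible with it.

The junction is decomposed canonically, V-greedy: V deletions are the
smallest count whose truncated germline suffix matches the read exactly
(extension capped at the J tag), then J deletions likewise given the V
attribution; the insert is what remains strictly between.  When junction
bases coincide with germline the decomposition is not unique, and the
canonical form attributes them to germline, V side first.  The simulator
canonicalizes ground truth with the same rule (`decombine.canonicalize`),
which is what makes exact table comparisons meaningful.

Per-read output is the 10-field record: five identifier fields, read id,
intertag sequence (first base after the V tag through last base before the
J tag) with qualities, and the 30-base UMI region with qualities.  The
pooled ratio of mismatching tag bases to inspected tag bases over accepted
hits is reported as a per-base error-rate lower bound.

## UMI collapsing

Thresholds (all configurable):

| parameter | default | meaning |
| --- | --- | --- |
| `min_umi_quality` | Phred 20 | minimum quality of each of the 12 UMI bases |
| `max_spacer_mismatches` | 2 per slot | spacer sanity check (ligation artifact gate) |
| `max_seq_divergence` | 0.10 | within-UMI per-base divergence below which sequences merge |
| `max_umi_mismatches` | 2 of 12 | UMI distance for across-UMI molecule merging |
| `max_tcr_mismatches` | 2 | intertag-sequence distance for "same TCR" across UMIs |

Sequence divergence between unequal-length sequences is Hamming distance
over the shared prefix plus one mismatch per missing base, divided by the
longer length; indel-producing errors are rare with proofreading
polymerases, so no alignment is attempted.  Within a UMI, distinct intertag
sequences are visited in descending read count (ties: lexicographically
smallest first, for determinism) and everything within the divergence
threshold of the current reference is absorbed into it; the reference — the
most frequent variant — is taken as the true sequence, since errors arise
late in PCR or in sequencing and appear as minor variants.  Across UMIs,
clusters carrying the same (or within `max_tcr_mismatches`) sequence under
UMIs within `max_umi_mismatches` are joined by single-linkage into
connected components; each component is one molecule, attributed to the
identifier of its most-supported member.  Clone size is the number of
components per identifier; reads absorbed per molecule is the PCR
amplification readout.

The scalable implementation blocks candidate pairs by pigeonhole chunking
(length-stratified, with the 30-base window anchored at the *end* of the
shared prefix, because V(D)J sequences share long germline prefixes and
differ at the junction).  Unit and acceptance tests verify exact agreement
with a literal quadratic implementation of the three steps.

## CDR3 extraction

The rearrangement is rebuilt as `V[:len−v_del] ∥ insert ∥ J[j_del:]` and
translated (standard nuclear code, Biopython) in the frame anchored at the
V gene's conserved-cysteine codon.  Productivity requires: both anchor
codons survive the deletions; the J anchor is congruent to the V anchor
mod 3 (otherwise `out_of_frame`); no stop codon at or before the J motif
(`stop_codon`); and both per-gene motif patterns match exactly at their
anchored positions, with `X` a wildcard (`missing_motif`).  Motif anchors
and patterns come from the reference's translate file rather than being
discovered by scanning, which keeps non-canonical motifs representable; no
fuzzy motif search is performed, so reference errors fail loudly.  The
CDR3 runs from the anchor cysteine through the FGXG phenylalanine,
inclusive.  `cdr3` output merges identifiers encoding the same CDR3;
`dcrcdr3` keeps one line per identifier.

## Repertoire statistics

Clone-size distributions are modeled as a discrete power law
f(x) = a·x^(−b) for x ≥ x_min.  The default estimator maximizes the exact
zeta likelihood numerically (bounded scalar minimization of
α·mean(ln x) + ln ζ(α, x_min) over α ∈ (1, 25]); the familiar closed form
1 + n/Σ ln(x_i/(x_min−½)) is available as `method="approx"` but is strongly
biased at x_min = 1 (its population value at b = 2 is ≈1.79), so it should
only be used for large cutoffs.  Automatic x_min minimizes the
Kolmogorov–Smirnov distance between the empirical tail and the fitted
model over the distinct observed sizes up to the 95th percentile, ties
toward the smaller cutoff.  A tail in which every observation equals x_min
is rejected as degenerate.  The matched sampler for estimator tests is the
zeta (Zipf) distribution via SciPy.

Diversity: Gini coefficient via the sorted-rank identity (equal to the
normalized mean absolute difference), Shannon entropy in nats (bits
optional), inverse Simpson as the effective clone number.  All are
sample-size dependent, so comparisons use `subsample`, which draws the
requested number of molecules uniformly without replacement (seeded).
Overlap removal deletes from a naive repertoire any clonotype present in a
memory set, keyed either by five-part identifier (nucleotide level,
default) or by CDR3 amino-acid string; annotated-CDR3 search returns the
query × repertoire abundance matrix with exact string matching.

## The simulator

The generator's role is to define study conditions with exact ground
truth.  Clones are drawn from the reference with geometric deletion counts
(mean 3, capped by each gene's tag bound) and geometric insert lengths
(mean 6, capped at 20, bases uniform) — simple distributions spanning the
identifier space, not a biological claim about junctional statistics.
Clone sizes (molecules per clone) follow `("powerlaw", b[, cap])`,
`("uniform", k)` or an explicit list; the optional cap matters because the
zeta law with b ≤ 2 has infinite mean, and it is what pins a dataset to its
nominal molecule scale for every seed.  Reads per molecule are lognormal
(configurable mean and log-σ, default mean 20, σ = 1), the two-parameter
stand-in for the very heterogeneous amplification observed per UMI in real
libraries.  Substitution errors are uniform per base; substituted bases
receive a low quality score (default Phred 10, `None` to disable),
modeling the error/quality correlation of real base calls.  Typical
per-cell transcript abundance (≈180 α, ≈400 β molecules per T cell) is
recorded in the config as context for cell-count arithmetic but the
desk-scale laws operate directly in molecules.

Two generator policies make error-free recovery exact *by construction*,
and they are the main caveat when extrapolating test results to real data:

* clone intertag sequences are redrawn to stay at least
  `min_clone_separation` (= UMI-merge radius + 1) mismatches apart, so
  molecule merging can never bridge distinct clones — real repertoires do
  contain clones 1–2 mismatches apart, which this pipeline (like any
  sequence-similarity collapser) would merge;
* UMIs are redrawn on global duplicates and on same-clone draws within the
  merge radius, so the molecule count of a clone is well defined — real
  libraries incur such birthday collisions at a low rate, biasing molecule
  counts slightly downward.

Both redraw counts are recorded in the ground truth.  The separation
policy implies a packing bound: 12-nt UMIs kept pairwise Hamming distance
≥3 apart cannot exceed ≈2.6×10⁴ per clone (sphere-packing of the 4¹²
barcode space), and random filling degrades well before that, so clone
sizes must stay a few thousand at most — the bundled power-law conditions
carry explicit caps for this reason, and the generator raises rather than
stalls if a draw cannot be separated.  Without the
quality-flagged-error model, reads carrying a UMI substitution form
"phantom" UMIs that single-linkage merging chains between legitimate UMIs,
conflating molecules; the Phred-20 UMI gate removes such reads, which is
precisely the failure mode the gate exists for.  Passing tests therefore
demonstrate correctness of the algorithms under the stated error model,
not immunity to indels, chimeras, or context-dependent error hotspots,
none of which are simulated.

Spike-in datasets mix `round(ratio × background_molecules)` molecules of a
fixed identifier into a power-law background trimmed to an exact molecule
total, one dataset per ratio.  Saturation curves subsample reads without
replacement at ascending depths and report collapsed molecule counts.

## Problem sizes

The bundled experiments run on one CPU in a few minutes: the error-free
round trip uses 10³ clones (truncated power law b = 1.8, cap 500, ≈10⁴
molecules) at mean amplification ×20 (~2×10⁵ reads); the error-correction
experiment 300 clones (cap 200) at ×50 and substitution rate 10⁻³; the
estimator-recovery experiments 10⁵ draws per exponent; the spike-in series
10⁵ background molecules per ratio at amplification ×1 across ratios
10⁻⁵…10⁻².

## Pipeline orchestration

`run_pipeline` executes the four stages per sample from one JSON config,
emits the exact config beside the outputs, aggregates logs, and fails with
the stage name on any error.  Each sample's chain comes from the sheet
row, a chain word in the sample name, or the pipeline default — none of
the three is a startup error.  One reference manifest serves a run;
multi-chain experiments run once per chain with the matching manifest.
Stage-by-stage manual execution with the same parameters is byte-identical
to the orchestrated run (tested).

## Known limitations

* No D-segment calling: beta/delta junction inserts contain D-derived
  nucleotides but the D gene is not identified.
* Single-strand search only; the amplicon orientation is fixed by the
  protocol, so no reverse-complement pass is made.
* No indel-aware comparison anywhere; indels shift the junction
  decomposition and typically surface as non-productive calls or distinct
  clonotypes.
* The conservative multi-gene no-call policy discards reads a
  priority-ordered tie-break might rescue.
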