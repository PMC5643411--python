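# umitcr

UMI-corrected analysis of T cell receptor (TCR) repertoire sequencing data.

T cell receptors are generated by somatic V(D)J recombination: a variable
(V) and a joining (J) gene segment are fused with nucleotides deleted from
their facing ends and untemplated nucleotides inserted at the junction.
Sequencing the resulting repertoire from bulk RNA is quantitatively
treacherous — PCR amplifies molecules very unevenly and introduces errors
that masquerade as rare clones.  Attaching a unique molecular identifier
(UMI) to every cDNA molecule before amplification fixes both problems:
reads sharing a UMI descend from one molecule, so their disagreements are
errors, and the number of distinct UMIs per receptor sequence is the true
molecule count ("clone size").

`umitcr` implements the complete computational side of such a protocol for
researchers running UMI-ligation TCR libraries on Illumina instruments:

1. **demultiplex** — reassemble R1/R2/I1 FASTQ triples into composite reads
   (first 30 bases of R2 = spacer/UMI region, both index hexamers, full R1)
   and split them per sample by dual index.
2. **decombine** — identify rearrangements by Aho–Corasick search for
   gene-specific V and J tags (one mismatch tolerated) and encode each as a
   five-part identifier `(V, J, V-deletions, J-deletions, insert)` that
   uniquely determines the rearranged nucleotide sequence.  Output records
   have 10 fields: the identifier, read id, intertag sequence + qualities,
   and UMI region + qualities.
3. **collapse** — UMI-based error correction: cluster near-identical
   intertag sequences within each UMI, then merge near-identical UMIs
   carrying the same receptor; report clonotypes with molecule-count
   abundances.
4. **cdr3** — rebuild the nucleotide rearrangement from each identifier,
   translate it in the V-gene frame, and extract the CDR3 (conserved V
   cysteine through the J "FGXG" phenylalanine), flagging out-of-frame,
   stop-codon and motif-less rearrangements as non-productive.

On top of the pipeline sit the repertoire statistics used to compare naive
and memory T cell compartments: clone-size spectra with discrete power-law
maximum-likelihood fits *f(x) = a·x^(−b)* (exact zeta MLE, automatic x_min
by Kolmogorov–Smirnov minimization), Gini coefficient, Shannon entropy and
inverse Simpson index with fixed-depth subsampling, naive-vs-memory overlap
removal, and annotated-CDR3 lookup (e.g. against VDJdb exports).  A
ground-truthed read simulator reproduces the full amplicon architecture —
power-law clone sizes, lognormal PCR amplification heterogeneity,
substitution errors, spike-in designs — so every stage is testable at desk
scale without touching external data.

## Worked example

A synthetic run from the bundled toy reference (4 V + 3 J genes), pushed
through assignment, collapsing, translation and statistics:

```python
from umitcr import toy_reference, SimConfig, simulate_repertoire
from umitcr.decombine import DecombineLog, decombine_stream
from umitcr.collapse import CollapseLog, collapse_records
from umitcr.cdr3 import translate_repertoire
from umitcr.repstats import (AbundanceDistribution, fit_power_law,
                             gini, shannon_entropy, inverse_simpson)

ref = toy_reference()
cfg = SimConfig(ref=ref, n_clones=200, seed=42,
                clone_size_law=("powerlaw", 2.0, 200),
                amplification=("lognormal", 10.0, 1.0),
                error_rate=0.001)
run = simulate_repertoire(cfg)

dec_log, col_log = DecombineLog(), CollapseLog()
records = decombine_stream(run.demultiplexed_stream(), ref, log=dec_log)
clones = collapse_records(records, log=col_log)
cdr3s, summary = translate_repertoire(clones, ref, mode="cdr3")

d = AbundanceDistribution.from_sizes(c.abundance for c in clones)
fit = fit_power_law(d, x_min=1)
```

which prints (via the f-strings in `examples` form):

```
simulated 5119 reads from 514 molecules in 200 clones
assigned 5117/5119 reads (error-rate lower bound 9.82e-04)
collapsed to 512 molecules in 203 clonotypes
63 productive CDR3s; most abundant: CASSESTSKCIKGLYASLPYPF (x48)
clone sizes: power-law exponent b = 2.15 (KS 0.017)
Gini 0.517, Shannon 4.644 nats, inverse Simpson 47.6
```

Reading the numbers: 5119 reads collapse back to 512 of the 514 generated
molecules (UMI correction undoes the ~10× amplification), the per-base
error rate estimated from tag mismatches matches the simulated 10⁻³, and
the fitted power-law exponent recovers the generating b = 2 from only 200
clones.  Roughly a third of random junctions are in-frame, hence 63
productive CDR3s.

## Command line

Every stage is also a subcommand of one CLI:

```bash
umitcr make-reference -o ref/                  # write the toy reference set
umitcr simulate --config sim.json -o data/     # ground-truthed FASTQ triples
umitcr demultiplex -r1 R1.fq.gz -r2 R2.fq.gz -i1 I1.fq.gz --sheet samples.csv -o out/
umitcr decombine -i out/donor1_beta.fq.gz --ref ref/toy.manifest.json
umitcr collapse -i out/donor1_beta.n12
umitcr cdr3 -i out/donor1_beta.freq --ref ref/toy.manifest.json
umitcr stats powerlaw out/donor1_beta.freq
umitcr run --config pipeline.json             # all stages in one call
```

File dialects follow the pipeline's conventions: `.n12` (10-field CSV per
assigned read), `.freq` (five identifier fields + abundance), `.cdr3` /
`.dcrcdr3` (CDR3 and frequency, with or without the identifier), plus
plain-text and CSV/JSON logs at every stage.

## Scope

D-segment identification, paired-chain (single-cell) analysis, indel-aware
error models and network-style UMI deduplication variants are out of scope.
The bundled reference is synthetic; real analyses load IMGT-derived
germline FASTA/tag/translate files through the same manifest interface.
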