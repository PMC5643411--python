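"""Germline V/J reference sets: loading, validation and indexing.

A reference set bundles, per chain, the germline V and J nucleotide
sequences, the short recognition tags used for gene assignment, and the
CDR3 motif anchors (the conserved cysteine codon near the 3' end of each V
gene; the phenylalanine codon of the "FGXG" motif in each J gene).

File dialects
-------------
* FASTA: one record per gene, header = gene name only.
* tags CSV: ``tag_sequence,tag_offset,gene_name``.
* translate CSV: ``gene_name,motif_anchor,motif_pattern``.
* manifest JSON: ``{"chain": ..., "species": ..., "fasta": ..., "tags": ...,
  "translate": ...}`` with file paths relative to the manifest.

All coordinates are 0-based, half-open.  Gene order in the FASTA defines the
integer V/J indices used throughout the pipeline, so the mapping from index
to IMGT-style name is simply load order within each segment class.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

CHAINS = ("alpha", "beta", "gamma", "delta")
MIN_TAG_LEN = 16

_VALID_SEQ = re.compile(r"^[ACGT]+$")


class ReferenceError(ValueError):
    """Raised when a reference set fails validation at load time."""


def segment_class_of(name: str) -> str:
    """Infer segment class (V or J) from an IMGT-style gene name.

    The first 'V' or 'J' character in the name decides (TRAV..., TRBJ...).
    """
    for ch in name:
        if ch in "VJ":
            return ch
    raise ReferenceError(f"cannot infer segment class from gene name {name!r}")


@dataclass(frozen=True)
class GermlineGene:
    name: str
    segment_class: str  # "V" or "J"
    sequence: str
    tag: str
    tag_offset: int
    motif_anchor: int
    motif_pattern: str  # "C" for V genes, "FGXG"-style for J genes

    def validate(self) -> None:
        if self.segment_class not in ("V", "J"):
            raise ReferenceError(f"{self.name}: bad segment class {self.segment_class!r}")
        if not _VALID_SEQ.match(self.sequence):
            raise ReferenceError(f"{self.name}: sequence contains non-ACGT characters")
        if len(self.tag) < MIN_TAG_LEN:
            raise ReferenceError(
                f"{self.name}: tag length {len(self.tag)} < {MIN_TAG_LEN}"
            )
        if self.sequence[self.tag_offset : self.tag_offset + len(self.tag)] != self.tag:
            raise ReferenceError(
                f"{self.name}: tag is not a substring of the gene sequence at "
                f"offset {self.tag_offset}"
            )
        if not (0 <= self.motif_anchor <= len(self.sequence) - 3):
            raise ReferenceError(f"{self.name}: motif anchor {self.motif_anchor} out of range")
        codon_aa = str(Seq(self.anchor_codon()).translate())
        if codon_aa != self.motif_pattern[0]:
            raise ReferenceError(
                f"{self.name}: anchor codon translates to {codon_aa!r}, "
                f"expected {self.motif_pattern[0]!r}"
            )

    def anchor_codon(self) -> str:
        return self.sequence[self.motif_anchor : self.motif_anchor + 3]

    @property
    def max_v_deletions(self) -> int:
        """Bases deletable from the 3' end without consuming the tag."""
        return len(self.sequence) - (self.tag_offset + len(self.tag))

    @property
    def max_j_deletions(self) -> int:
        """Bases deletable from the 5' end without consuming the tag."""
        return self.tag_offset


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ReferenceSet:
    chain: str
    species: str
    v_genes: tuple[GermlineGene, ...]
    j_genes: tuple[GermlineGene, ...] = field(default=())

    def validate(self) -> None:
        if self.chain not in CHAINS:
            raise ReferenceError(f"unknown chain {self.chain!r}")
        for gene in (*self.v_genes, *self.j_genes):
            gene.validate()
        for cls, genes in (("V", self.v_genes), ("J", self.j_genes)):
            for g in genes:
                if g.segment_class != cls:
                    raise ReferenceError(f"{g.name}: listed as {cls} gene but class is {g.segment_class}")
            for i, a in enumerate(genes):
                for b in genes[i + 1 :]:
                    if len(a.tag) == len(b.tag) and _hamming(a.tag, b.tag) <= 1:
                        raise ReferenceError(
                            f"tag collision within class {cls}: {a.name} and {b.name} "
                            f"have tags within Hamming distance 1 "
                            f"(single-mismatch matching would be ambiguous)"
                        )

    def genes(self, segment_class: str) -> tuple[GermlineGene, ...]:
        if segment_class == "V":
            return self.v_genes
        if segment_class == "J":
            return self.j_genes
        raise ReferenceError(f"bad segment class {segment_class!r}")

    def index_to_name(self, segment_class: str, index: int) -> str:
        genes = self.genes(segment_class)
        if not (0 <= index < len(genes)):
            raise IndexError(
                f"{segment_class} index {index} out of range 0..{len(genes) - 1}"
            )
        return genes[index].name

    def name_table(self) -> dict[str, list[str]]:
        """Export the index -> name mapping for both segment classes."""
        return {
            "V": [g.name for g in self.v_genes],
            "J": [g.name for g in self.j_genes],
        }


def load_reference_set(
    fasta_path: str | Path,
    tag_path: str | Path,
    translate_path: str | Path,
    chain: str,
    species: str = "unspecified",
) -> ReferenceSet:
    """Load and validate a reference set from its three companion files.

    Gene order in the FASTA defines the V and J indices.  Every gene must
    appear in all three files; any inconsistency is a load error naming the
    offending gene.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ReferenceError(f"no FASTA records in {fasta_path}")
    seqs: dict[str, str] = {}
    order: list[str] = []
    for rec in records:
        name = rec.id
        if name in seqs:
            raise ReferenceError(f"duplicate FASTA record for gene {name}")
        seqs[name] = str(rec.seq).upper()
        order.append(name)

    tags: dict[str, tuple[str, int]] = {}
    with open(tag_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            tag_seq, tag_offset, gene_name = row[0], int(row[1]), row[2]
            if gene_name in tags:
                raise ReferenceError(f"duplicate tag entry for gene {gene_name}")
            tags[gene_name] = (tag_seq.upper(), tag_offset)

    motifs: dict[str, tuple[int, str]] = {}
    with open(translate_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            gene_name, anchor, pattern = row[0], int(row[1]), row[2]
            if gene_name in motifs:
                raise ReferenceError(f"duplicate translate entry for gene {gene_name}")
            motifs[gene_name] = (anchor, pattern.upper())

    for label, present in (("tag", tags), ("translate", motifs)):
        missing = [n for n in order if n not in present]
        extra = [n for n in present if n not in seqs]
        if missing:
            raise ReferenceError(f"gene {missing[0]} missing from {label} file")
        if extra:
            raise ReferenceError(f"gene {extra[0]} in {label} file has no FASTA record")

    v_genes: list[GermlineGene] = []
    j_genes: list[GermlineGene] = []
    for name in order:
        cls = segment_class_of(name)
        tag_seq, tag_offset = tags[name]
        anchor, pattern = motifs[name]
        gene = GermlineGene(
            name=name,
            segment_class=cls,
            sequence=seqs[name],
            tag=tag_seq,
            tag_offset=tag_offset,
            motif_anchor=anchor,
            motif_pattern=pattern,
        )
        (v_genes if cls == "V" else j_genes).append(gene)

    ref = ReferenceSet(chain=chain, species=species, v_genes=tuple(v_genes), j_genes=tuple(j_genes))
    ref.validate()
    return ref


def load_manifest(manifest_path: str | Path) -> ReferenceSet:
    """Load a reference set via its JSON manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    return load_reference_set(
        base / manifest["fasta"],
        base / manifest["tags"],
        base / manifest["translate"],
        chain=manifest["chain"],
        species=manifest.get("species", "unspecified"),
    )


def write_reference_set(ref: ReferenceSet, outdir: str | Path, stem: str = "reference") -> Path:
    """Write a reference set as FASTA + tags CSV + translate CSV + manifest.

    Returns the manifest path.  Round-trips through :func:`load_manifest`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{stem}.fasta"
    tags = outdir / f"{stem}.tags.csv"
    translate = outdir / f"{stem}.translate.csv"
    genes = [*ref.v_genes, *ref.j_genes]
    with open(fasta, "w") as fh:
        for g in genes:
            fh.write(f">{g.name}\n{g.sequence}\n")
    with open(tags, "w", newline="") as fh:
        w = csv.writer(fh)
        for g in genes:
            w.writerow([g.tag, g.tag_offset, g.name])
    with open(translate, "w", newline="") as fh:
        w = csv.writer(fh)
        for g in genes:
            w.writerow([g.name, g.motif_anchor, g.motif_pattern])
    manifest = outdir / f"{stem}.manifest.json"
    with open(manifest, "w") as fh:
        json.dump(
            {
                "chain": ref.chain,
                "species": ref.species,
                "fasta": fasta.name,
                "tags": tags.name,
                "translate": translate.name,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Bundled synthetic toy reference (4 V + 3 J genes).
#
# Architecture: V genes are 93 nt, in frame 0 with no stops, with a 21-nt tag
# at offset 39 and the conserved cysteine codon TGT at position 81 (the gene
# ends ...TGT GCC AGC AGC, i.e. C A S S).  J genes are 60 nt with 8 deletable
# 5' bases, a 21-nt tag at offset 8 and an FGXG motif (TTC GGC ACA GGC) at
# position 33.  Tags are pairwise Hamming distance >= 5 so single-mismatch
# matching is unambiguous.  Synthetic sequences; not IMGT germline.
# ---------------------------------------------------------------------------

_TOY_V = [
    ("TRBV9-1*01", "TTGCCCGCATACCGGATAAAGAATGCCACTGTTATGATAGACATGCGACGACTGGCCCCAACAAGGGGAACACGTCAGCTATGTGCCAGCAGC"),
    ("TRBV9-2*01", "CGGTGGTACGGTCTCTGTTTATTTTGTGCATATGGACATCCGGTAAGACCATTTAAGGCCGATGTGGCGTGCACGGAGAACTGTGCCAGCAGC"),
    ("TRBV9-3*01", "TCGGGTACCTGTCAGCCCCCGCAGACTGATTCAGATAACAAGGAACAGCATACGACACGACATCTAGGGCGAGTACTTGACTGTGCCAGCAGC"),
    ("TRBV9-4*01", "GCATCTGCAACTTCCTTCTCAACAATCTGTCTAGCGAGCCGGGGCCACTACCTATTGAGGGTGTCCTACAGCCAAGGCGATTGTGCCAGCAGC"),
]
_TOY_J = [
    ("TRBJ2-1*01", "GTGCACTCACTTTTTATATCGTGCAAGGAGTCTTTCGGCACAGGCTTATCGTTCCAATGT"),
    ("TRBJ2-2*01", "GGGGCTCCATCTGGCCGATATTCTGGATCCGACTTCGGCACAGGCTCTATCGTACTATCA"),
    ("TRBJ2-3*01", "ATTAAAGGACTCTATGCCAGTTTGCCTTACCCGTTCGGCACAGGCCGGGGATTGACCAGC"),
]
TOY_V_TAG_OFFSET = 39
TOY_V_TAG_LEN = 21
TOY_V_ANCHOR = 81
TOY_J_TAG_OFFSET = 8
TOY_J_TAG_LEN = 21
TOY_J_ANCHOR = 33


def toy_reference(chain: str = "beta") -> ReferenceSet:
    """The bundled 4V + 3J synthetic reference used for tests and examples."""
    v_genes = tuple(
        GermlineGene(
            name=name,
            segment_class="V",
            sequence=seq,
            tag=seq[TOY_V_TAG_OFFSET : TOY_V_TAG_OFFSET + TOY_V_TAG_LEN],
            tag_offset=TOY_V_TAG_OFFSET,
            motif_anchor=TOY_V_ANCHOR,
            motif_pattern="C",
        )
        for name, seq in _TOY_V
    )
    j_genes = tuple(
        GermlineGene(
            name=name,
            segment_class="J",
            sequence=seq,
            tag=seq[TOY_J_TAG_OFFSET : TOY_J_TAG_OFFSET + TOY_J_TAG_LEN],
            tag_offset=TOY_J_TAG_OFFSET,
            motif_anchor=TOY_J_ANCHOR,
            motif_pattern="FGXG",
        )
        for name, seq in _TOY_J
    )
    ref = ReferenceSet(chain=chain, species="synthetic", v_genes=v_genes, j_genes=j_genes)
    ref.validate()
    return ref
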