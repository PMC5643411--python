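"""Ground-truthed synthetic sequencing runs for the full pipeline.

The generator emulates the amplicon architecture of the library protocol:
each cDNA molecule carries a 12-nt UMI in two 6-nt slots separated by
8-base spacers (read as the first 30 bases of R2), while R1 starts with 6
random bases, the 6-base sample index, a constant-region stub and the
rearranged V(D)J sequence.  Clones are drawn from the toy (or any) germline
reference with geometric junctional deletions and inserts; clone sizes (in
molecules) follow a configurable law, power law by default; per-molecule
read counts follow a lognormal law capturing PCR amplification
heterogeneity; substitution errors are applied uniformly per base.

Ground truth records every molecule and the canonical identifier of every
clone, so pipeline output can be compared exactly.  Two generator policies
keep the error-free round trip exact by construction: clones are redrawn
when their intertag sequence comes within ``min_clone_separation``
mismatches of an existing clone (legitimate UMI merging could otherwise
bridge them), and UMIs are redrawn on a birthday collision (global
duplicate, or near-duplicate within one clone); both redraw tallies are
kept in the truth object.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from scipy import stats

from . import layout
from .cdr3 import extract_cdr3
from .collapse import DEFAULT_UMI_MISMATCHES, SequenceNeighborIndex, mismatch_count
from .decombine import TcrIdentifier, canonicalize, reconstruct
from .io import open_text, write_fastq_record
from .references import ReferenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# clone size laws: ("powerlaw", b) | ("uniform", k) | ("explicit", [sizes])
# amplification laws: ("lognormal", mean, sigma_log) | ("constant", k)


@dataclass
class SimConfig:
    ref: ReferenceSet
    n_clones: int
    seed: int  # mandatory: every dataset is reproducible by construction
    clone_size_law: tuple = ("powerlaw", 2.0)
    amplification: tuple = ("lognormal", 20.0, 1.0)
    error_rate: float = 0.0
    spacer1: str = layout.DEFAULT_SPACER1
    spacer2: str = layout.DEFAULT_SPACER2
    sample_index1: str = "ATCACG"
    sample_index2: str = "CGATGT"
    r1_length: int = 251
    r2_length: int = 100
    quality_phred: int = 35
    # mean junctional geometry (truncated geometric draws)
    mean_deletions: float = 3.0
    mean_insert_length: float = 6.0
    max_insert_length: int = 20
    # protocol context: measured TCR transcripts per cell (~180 alpha /
    # ~400 beta); metadata for cell-count arithmetic, not used in molecule-
    # level size laws.
    molecules_per_cell: int = 100
    min_clone_separation: int = DEFAULT_UMI_MISMATCHES + 1
    # same-clone UMIs are drawn outside the UMI-merge radius so that the
    # molecule count of a clone is well defined under collapsing
    umi_clone_separation: int = DEFAULT_UMI_MISMATCHES + 1
    # quality assigned to substituted bases: sequencer miscalls carry low
    # confidence, which is what downstream quality gating keys on.  Set to
    # None for constant quality (errors then look like PCR errors).
    error_quality_phred: int | None = 10

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be in [0, 1]")
        for sp in (self.spacer1, self.spacer2):
            if len(sp) != layout.SPACER_LEN:
                raise ValueError(f"spacers must be {layout.SPACER_LEN} nt")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")

    def to_json(self, path: str | Path) -> None:
        d = {k: v for k, v in self.__dict__.items() if k != "ref"}
        d["ref"] = {"chain": self.ref.chain, "species": self.ref.species}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=list)
            fh.write("\n")


class SimRead(NamedTuple):
    read_id: str
    r1: str
    r1_qual: str
    r2: str
    r2_qual: str
    i1: str
    i1_qual: str


class MoleculeTruth(NamedTuple):
    molecule_index: int
    clone_index: int
    umi: str
    n_reads: int


@dataclass
class CloneTruth:
    clone_index: int
    identifier: TcrIdentifier  # canonical form
    n_molecules: int


@dataclass
class GroundTruth:
    clones: list[CloneTruth]
    molecules: list[MoleculeTruth]
    umi_redraws: int = 0
    clone_redraws: int = 0
    sample_name: str = "sim"

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def clone_table(self) -> dict[TcrIdentifier, int]:
        """Canonical identifier -> molecule count."""
        return {c.identifier: c.n_molecules for c in self.clones if c.n_molecules}

    def cdr3_table(self, ref: ReferenceSet) -> dict[str, int]:
        """Productive CDR3 -> summed molecule count."""
        table: Counter[str] = Counter()
        for c in self.clones:
            rec = extract_cdr3(c.identifier, ref, frequency=c.n_molecules)
            if rec.productive and c.n_molecules:
                table[rec.cdr3_aa] += c.n_molecules
        return dict(table)

    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        with open(outdir / "truth.clones.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["clone_index", "v", "j", "v_del", "j_del", "insert", "n_molecules"])
            for c in self.clones:
                i = c.identifier
                w.writerow([c.clone_index, i.v_index, i.j_index, i.v_deletions,
                            i.j_deletions, i.insert, c.n_molecules])
        with open(outdir / "truth.molecules.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["molecule_index", "clone_index", "umi", "n_reads"])
            for m in self.molecules:
                w.writerow(list(m))


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _truncated_geometric(rng: np.random.Generator, mean: float, cap: int) -> int:
    if cap <= 0:
        return 0
    draw = rng.geometric(1.0 / (mean + 1.0)) - 1
    return int(min(draw, cap))


def _intertag_sequence(ident: TcrIdentifier, ref: ReferenceSet) -> str:
    """Intertag sequence of a rearrangement: bases between the V tag end and
    the J tag start, as assignment would report it on an error-free read."""
    seq = reconstruct(ident, ref)
    v_gene = ref.v_genes[ident.v_index]
    j_gene = ref.j_genes[ident.j_index]
    v_tag_end = v_gene.tag_offset + len(v_gene.tag)
    j_tag_start = (
        len(seq)
        - (len(j_gene.sequence) - ident.j_deletions)
        + (j_gene.tag_offset - ident.j_deletions)
    )
    return seq[v_tag_end:j_tag_start]


def draw_clone(
    rng: np.random.Generator,
    cfg: SimConfig,
    neighbors: SequenceNeighborIndex,
    max_rearrangement_length: int,
) -> tuple[TcrIdentifier, int]:
    """One new canonical clone identifier, redrawn until it is well
    separated from existing clones and fits the read.  Returns the
    identifier and the number of redraws it took."""
    ref = cfg.ref
    redraws = 0
    while True:
        v = int(rng.integers(len(ref.v_genes)))
        j = int(rng.integers(len(ref.j_genes)))
        v_gene, j_gene = ref.v_genes[v], ref.j_genes[j]
        v_del = _truncated_geometric(rng, cfg.mean_deletions, v_gene.max_v_deletions)
        j_del = _truncated_geometric(rng, cfg.mean_deletions, j_gene.max_j_deletions)
        ins_len = _truncated_geometric(rng, cfg.mean_insert_length, cfg.max_insert_length)
        insert = _rand_bases(rng, ins_len)
        ident = canonicalize(TcrIdentifier(v, j, v_del, j_del, insert), ref)
        seq = reconstruct(ident, ref)
        intertag = _intertag_sequence(ident, ref)
        if len(seq) <= max_rearrangement_length and not neighbors.has_neighbor(intertag):
            neighbors.add(intertag)
            return ident, redraws
        redraws += 1


def _clone_sizes(rng: np.random.Generator, cfg: SimConfig) -> list[int]:
    # powerlaw takes an optional truncation cap ("powerlaw", b, max_size):
    # for exponents <= 2 the untruncated zeta law has infinite mean, so a
    # cap is what keeps a dataset's molecule count at its nominal scale
    law = cfg.clone_size_law
    if law[0] == "powerlaw":
        draws = stats.zipf.rvs(law[1], size=cfg.n_clones, random_state=rng)
        if len(law) > 2:
            draws = np.minimum(draws, int(law[2]))
        return [int(x) for x in draws]
    if law[0] == "uniform":
        return [int(law[1])] * cfg.n_clones
    if law[0] == "explicit":
        return [int(x) for x in law[1]]
    raise ValueError(f"unknown clone size law {law[0]!r}")


def _reads_per_molecule(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    law = cfg.amplification
    if law[0] == "constant":
        return np.full(n, int(law[1]), dtype=np.int64)
    if law[0] == "lognormal":
        mean, sigma = float(law[1]), float(law[2])
        mu = np.log(mean) - sigma**2 / 2.0
        draws = np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
        return np.maximum(draws, 1)
    raise ValueError(f"unknown amplification law {law[0]!r}")


def _apply_errors(
    seq: str,
    qual: str,
    rng: np.random.Generator,
    rate: float,
    error_qual: str | None,
) -> tuple[str, str]:
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq, qual
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    positions = rng.choice(len(seq), size=k, replace=False)
    # substitute with a uniformly chosen *different* base
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    if error_qual is not None:
        q = np.frombuffer(qual.encode(), dtype=np.uint8).copy()
        q[positions] = ord(error_qual)
        qual = q.tobytes().decode()
    return arr.tobytes().decode(), qual


@dataclass
class SimulatedRun:
    truth: GroundTruth
    reads: list[SimRead]

    def demultiplexed_stream(self) -> Iterator[tuple[str, str, str]]:
        """(id, seq, qual) stream matching the demultiplexer's per-sample
        output contract (30-base UMI region prepended to R1)."""
        u = layout.UMI_REGION_LEN
        for r in self.reads:
            yield r.read_id, r.r2[:u] + r.r1, r.r2_qual[:u] + r.r1_qual

    def write_fastq(self, outdir: str | Path, gzip_output: bool = True) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = ".fq.gz" if gzip_output else ".fq"
        paths = {k: outdir / f"{self.truth.sample_name}_{k}{ext}" for k in ("R1", "R2", "I1")}
        with open_text(paths["R1"], "wt") as f1, open_text(paths["R2"], "wt") as f2, \
                open_text(paths["I1"], "wt") as fi:
            for r in self.reads:
                write_fastq_record(f1, r.read_id, r.r1, r.r1_qual)
                write_fastq_record(f2, r.read_id, r.r2, r.r2_qual)
                write_fastq_record(fi, r.read_id, r.i1, r.i1_qual)
        return paths


def _emit_molecule_reads(
    reads: list[SimRead],
    rng: np.random.Generator,
    cfg: SimConfig,
    rearrangement: str,
    umi: str,
    molecule_index: int,
    n_reads: int,
) -> None:
    q = chr(33 + cfg.quality_phred)
    eq = None if cfg.error_quality_phred is None else chr(33 + cfg.error_quality_phred)
    h = layout.UMI_HALF_LEN
    r2_core = cfg.spacer1 + umi[:h] + cfg.spacer2 + umi[h:]
    r1_core_len = layout.RANDOM_PREFIX_LEN + layout.INDEX_LEN + len(layout.CONST_REGION_STUB) + len(rearrangement)
    r1_fill = cfg.r1_length - r1_core_len
    r2_fill = cfg.r2_length - len(r2_core)
    per_read = layout.RANDOM_PREFIX_LEN + max(r1_fill, 0) + max(r2_fill, 0)
    pool = _rand_bases(rng, per_read * n_reads)  # one RNG call per molecule
    for r in range(n_reads):
        o = r * per_read
        r1 = (
            pool[o : o + layout.RANDOM_PREFIX_LEN]
            + cfg.sample_index2
            + layout.CONST_REGION_STUB
            + rearrangement
            + (pool[o + layout.RANDOM_PREFIX_LEN : o + layout.RANDOM_PREFIX_LEN + r1_fill] if r1_fill > 0 else "")
        )
        r2 = r2_core + (pool[o + per_read - r2_fill : o + per_read] if r2_fill > 0 else "")
        i1 = cfg.sample_index1
        r1q, r2q, i1q = q * len(r1), q * len(r2), q * len(i1)
        if cfg.error_rate > 0.0:
            r1, r1q = _apply_errors(r1, r1q, rng, cfg.error_rate, eq)
            r2, r2q = _apply_errors(r2, r2q, rng, cfg.error_rate, eq)
            i1, i1q = _apply_errors(i1, i1q, rng, cfg.error_rate, eq)
        reads.append(
            SimRead(f"sim.m{molecule_index}.r{r}", r1, r1q, r2, r2q, i1, i1q)
        )


class _UmiNeighborSet:
    """Pigeonhole-bucketed set of one clone's UMIs supporting fast
    "anything within the separation radius?" queries."""

    def __init__(self, radius: int):
        self.radius = radius
        n = radius + 1
        self._chunk = max(1, layout.UMI_LEN // n)
        self._buckets: dict[tuple[int, str], list[str]] = {}

    def _keys(self, umi: str):
        c = self._chunk
        return [(k, umi[k * c : (k + 1) * c]) for k in range(self.radius + 1)]

    def near(self, umi: str) -> bool:
        r = self.radius
        for key in self._keys(umi):
            for other in self._buckets.get(key, ()):
                if mismatch_count(umi, other, r) <= r:
                    return True
        return False

    def add(self, umi: str) -> None:
        for key in self._keys(umi):
            self._buckets.setdefault(key, []).append(umi)


def _draw_umi(
    rng: np.random.Generator,
    clone_umis: _UmiNeighborSet,
    all_umis: set[str],
    truth: GroundTruth,
) -> str:
    """A fresh 12-nt UMI, redrawn on a global duplicate or a same-clone
    near-duplicate (within the clone separation radius).

    The separation policy bounds how many UMIs one clone can hold (a
    Hamming-packing constraint of the 12-nt barcode space); rather than
    stall when a clone approaches that bound, the draw fails loudly.
    """
    for _ in range(2000):
        umi = _rand_bases(rng, layout.UMI_LEN)
        if umi not in all_umis and not clone_umis.near(umi):
            all_umis.add(umi)
            clone_umis.add(umi)
            return umi
        truth.umi_redraws += 1
    raise RuntimeError(
        "could not draw a separated UMI after 2000 attempts: the clone size "
        "approaches the packing capacity of the 12-nt UMI space at this "
        "separation radius; reduce clone sizes or umi_clone_separation"
    )


def simulate_repertoire(
    cfg: SimConfig,
    clone_sizes: Sequence[int] | None = None,
    extra_clones: Sequence[tuple[TcrIdentifier, int]] | None = None,
) -> SimulatedRun:
    """Generate a full R1/R2/I1 run with ground truth.

    ``clone_sizes`` overrides the configured clone-size law (sizes are
    molecules per clone); ``extra_clones`` prepends fixed (identifier,
    molecules) clones such as spike-ins, exempt from the separation check
    against nothing (they seed the neighbor index first).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    max_rearr = (
        cfg.r1_length
        - layout.RANDOM_PREFIX_LEN
        - layout.INDEX_LEN
        - len(layout.CONST_REGION_STUB)
    )
    truth = GroundTruth(clones=[], molecules=[])
    neighbors = SequenceNeighborIndex(cfg.min_clone_separation - 1)

    clone_specs: list[tuple[TcrIdentifier, int]] = []
    for ident, n_mol in extra_clones or ():
        ident = canonicalize(ident, cfg.ref)
        neighbors.add(_intertag_sequence(ident, cfg.ref))
        clone_specs.append((ident, n_mol))
    sizes = list(clone_sizes) if clone_sizes is not None else _clone_sizes(rng, cfg)
    for size in sizes:
        ident, redraws = draw_clone(rng, cfg, neighbors, max_rearr)
        truth.clone_redraws += redraws
        clone_specs.append((ident, size))

    reads: list[SimRead] = []
    all_umis: set[str] = set()
    molecule_index = 0
    for clone_index, (ident, n_mol) in enumerate(clone_specs):
        truth.clones.append(CloneTruth(clone_index, ident, n_mol))
        rearrangement = reconstruct(ident, cfg.ref)
        clone_umis = _UmiNeighborSet(cfg.umi_clone_separation - 1)
        read_counts = _reads_per_molecule(rng, cfg, n_mol)
        for m in range(n_mol):
            umi = _draw_umi(rng, clone_umis, all_umis, truth)
            n_reads = int(read_counts[m])
            _emit_molecule_reads(reads, rng, cfg, rearrangement, umi, molecule_index, n_reads)
            truth.molecules.append(MoleculeTruth(molecule_index, clone_index, umi, n_reads))
            molecule_index += 1
    return SimulatedRun(truth, reads)


@dataclass
class SpikeinDataset:
    ratio: float
    spike_molecules: int
    run: SimulatedRun
    spike_identifier: TcrIdentifier


def simulate_spikein(
    cfg: SimConfig,
    background_molecules: int,
    spike_identifier: TcrIdentifier,
    ratios: Sequence[float],
) -> list[SpikeinDataset]:
    """One dataset per spike:background ratio.

    Background clone sizes are drawn from the configured law and trimmed to
    exactly ``background_molecules``; the spike clone contributes
    ``round(ratio * background_molecules)`` molecules.
    """
    for r in ratios:
        if not (0.0 < r <= 1.0):
            raise ValueError(f"ratio {r} outside (0, 1]")
    rng = np.random.default_rng(cfg.seed)
    law = cfg.clone_size_law
    sizes: list[int] = []
    total = 0
    while total < background_molecules:
        if law[0] == "powerlaw":
            batch = stats.zipf.rvs(law[1], size=1024, random_state=rng)
            if len(law) > 2:
                batch = np.minimum(batch, int(law[2]))
        elif law[0] == "uniform":
            batch = np.full(1024, int(law[1]))
        else:
            raise ValueError("spike-in backgrounds need a powerlaw or uniform size law")
        for size in batch:
            size = int(min(size, background_molecules - total))
            sizes.append(size)
            total += size
            if total >= background_molecules:
                break

    spike_identifier = canonicalize(spike_identifier, cfg.ref)
    datasets = []
    for k, ratio in enumerate(ratios):
        spike_molecules = int(round(ratio * background_molecules))
        sub_cfg = SimConfig(**{**cfg.__dict__, "seed": cfg.seed + 1 + k, "n_clones": len(sizes)})
        run = simulate_repertoire(
            sub_cfg,
            clone_sizes=sizes,
            extra_clones=[(spike_identifier, spike_molecules)],
        )
        run.truth.sample_name = f"spike_{k}"
        datasets.append(SpikeinDataset(ratio, spike_molecules, run, spike_identifier))
    return datasets


def saturation_curve(
    run: SimulatedRun,
    read_depths: Sequence[int],
    ref: ReferenceSet,
    seed: int = 0,
):
    """Distinct UMI-defined molecules recovered at each read depth.

    Reads are subsampled without replacement to each depth (capped at the
    total, flagged), assigned and collapsed.  Returns a DataFrame with
    columns depth, requested_depth, capped, molecules; molecule counts are
    non-decreasing in depth up to subsampling noise.
    """
    import pandas as pd

    from .collapse import CollapseLog, collapse_records
    from .decombine import DecombineLog, TagMatcher, decombine_stream

    if list(read_depths) != sorted(read_depths):
        raise ValueError("read depths must be ascending")
    rng = np.random.default_rng(seed)
    matcher = TagMatcher(ref)
    u = layout.UMI_REGION_LEN
    composed = [
        (r.read_id, r.r2[:u] + r.r1, r.r2_qual[:u] + r.r1_qual) for r in run.reads
    ]
    rows = []
    for requested in read_depths:
        depth = min(int(requested), len(composed))
        idx = rng.choice(len(composed), size=depth, replace=False)
        subset = [composed[i] for i in sorted(idx)]
        log = CollapseLog()
        collapse_records(
            decombine_stream(subset, ref, matcher=matcher, log=DecombineLog()),
            log=log,
        )
        rows.append(
            {
                "depth": depth,
                "requested_depth": int(requested),
                "capped": depth < int(requested),
                "molecules": log.n_molecules,
            }
        )
    return pd.DataFrame(rows)
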