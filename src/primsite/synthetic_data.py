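"""Synthetic data generation for Sleeping Beauty (SB100x) integration-site analysis.

Everything the downstream analysis consumes can be simulated here with
controlled statistical structure: a multi-chromosome reference genome, a
gene model with TSS/UTR/CDS/intron structure, an IR/DR-flanked transposon,
TA-dinucleotide-restricted integration events (optionally with hotspot
enrichment), junction-spanning reads with substitution errors, and random
TA-containing genomic fragments for the randomized null.

SB100x integrates its cargo exclusively at TA dinucleotides and duplicates
the TA, so both vector-chromosome junctions read TA; the constructed
integrated sequence reproduces that signature exactly.

All randomness flows from a single integer seed through per-purpose child
streams, so identical configurations give byte-identical outputs regardless
of which operations are invoked or in what order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .io import FastqRead, revcomp

__all__ = [
    "ConfigurationError",
    "CapacityError",
    "PlacementError",
    "JunctionError",
    "ReferenceGenome",
    "Gene",
    "GeneModel",
    "TransposonModel",
    "IntegrationEvent",
    "SimulationConfig",
    "sb100x_transposon",
    "find_ta_positions",
    "generate_genome",
    "generate_gene_model",
    "simulate_integrations",
    "construct_integrated_sequence",
    "generate_junction_reads",
    "generate_random_ta_fragments",
    "write_gff3",
    "read_gff3",
]


class ConfigurationError(ValueError):
    """A simulation parameter is out of its documented range."""


class CapacityError(ValueError):
    """The genome cannot supply as many distinct sites/fragments as requested."""


class PlacementError(RuntimeError):
    """Genes cannot be placed without overlap at the requested density."""


class JunctionError(ValueError):
    """An integration position does not sit on a reference TA dinucleotide."""


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Child generator for one purpose, stable under call order."""
    return np.random.default_rng([int(seed), zlib.crc32(tag.encode())])


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class ReferenceGenome:
    """Ordered chromosome name -> uppercase A/C/G/T sequence."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigurationError("genome must contain at least one chromosome")
        allowed = set("ACGT")
        for name, seq in self.chromosomes.items():
            if not name:
                raise ConfigurationError("chromosome names must be nonempty")
            if not seq:
                raise ConfigurationError(f"chromosome {name!r} has empty sequence")
            if set(seq) - allowed:
                bad = sorted(set(seq) - allowed)
                raise ConfigurationError(
                    f"chromosome {name!r} contains characters outside ACGT: {bad}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass
class Gene:
    """One single-transcript gene on the forward-strand coordinate system.

    ``start``/``end`` bound the transcript span (0-based half-open); ``cds``,
    ``utr5`` and ``utr3`` are disjoint interval lists inside the span.
    Introns are the within-span gaps between exonic (CDS plus UTR) intervals.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def exonic_intervals(self) -> list[tuple[int, int]]:
        return sorted(self.cds + self.utr5 + self.utr3)

    def introns(self) -> list[tuple[int, int]]:
        exons = self.exonic_intervals()
        out = []
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return out


@dataclass
class GeneModel:
    genes: list[Gene]

    def by_chromosome(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chromosome, []).append(g)
        return out

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class TransposonModel:
    """IR/DR-flanked transposon: terminal repeats plus an internal cargo.

    ``cargo`` may be given explicitly (e.g. with embedded iPCR primer
    cassettes); otherwise a fixed pseudo-random non-genomic filler of
    ``cargo_length`` bases is derived from ``label``, so reads never
    multimap into cargo.
    """

    left_end: str
    right_end: str
    cargo_length: int
    label: str = "SB"
    cargo: str | None = None

    def __post_init__(self) -> None:
        if len(self.left_end) < 50 or len(self.right_end) < 50:
            raise ConfigurationError("IR/DR ends must each be at least 50 bp")
        if self.left_end == self.right_end:
            raise ConfigurationError("left and right IR/DR ends must be distinct")
        if self.cargo_length < 0:
            raise ConfigurationError("cargo_length must be >= 0")
        if self.cargo is not None and len(self.cargo) != self.cargo_length:
            raise ConfigurationError("explicit cargo length disagrees with cargo_length")

    def cargo_sequence(self) -> str:
        if self.cargo is not None:
            return self.cargo
        rng = np.random.default_rng(zlib.crc32(f"cargo:{self.label}".encode()))
        return _random_dna(rng, self.cargo_length, gc=0.5)

    def total_length(self) -> int:
        return len(self.left_end) + self.cargo_length + len(self.right_end)

    def check_against_genome(self, genome: ReferenceGenome) -> None:
        """IR/DR ends must not occur in the genome (simulation-time invariant)."""
        for name, seq in genome.chromosomes.items():
            for endseq in (self.left_end, self.right_end):
                if endseq in seq or revcomp(endseq) in seq:
                    raise ConfigurationError(
                        f"transposon end occurs in chromosome {name}; "
                        "choose different end sequences"
                    )


@dataclass(frozen=True)
class IntegrationEvent:
    """A single TA-targeted insertion; ``position`` is the 0-based index of
    the T of the target TA on the forward strand."""

    chromosome: str
    position: int
    orientation: str
    event_id: str


@dataclass
class SimulationConfig:
    """Every knob of the simulator, with the study's default conditions.

    Defaults describe a 10 Mb four-chromosome genome at mouse-like GC
    (0.42) carrying 200 integrations, with 80 bp junction reads bearing a
    20 bp IR/DR terminal signature and error-free bases.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_lengths: tuple[int, ...] | int = 2_500_000
    gc_fraction: float = 0.42
    n_genes: int = 100
    n_integrations: int = 200
    hotspot_spec: list[tuple[tuple[str, int, int], float]] | None = None
    read_length: int = 80
    reads_per_event: int = 3
    substitution_error_rate: float = 0.0
    end_match_length: int = 20
    n_random_fragments: int | None = None  # default: n_integrations
    random_fragment_length: int = 60

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_error_rate < 0.25):
            raise ConfigurationError("substitution_error_rate must be in [0, 0.25)")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ConfigurationError("gc_fraction must be in [0, 1]")
        if self.hotspot_spec:
            for _, mult in self.hotspot_spec:
                if mult <= 0:
                    raise ConfigurationError("hotspot weight multipliers must be > 0")
        if self.n_chromosomes < 1:
            raise ConfigurationError("need at least one chromosome")

    @property
    def lengths(self) -> tuple[int, ...]:
        if isinstance(self.chromosome_lengths, int):
            return tuple([self.chromosome_lengths] * self.n_chromosomes)
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ConfigurationError("chromosome_lengths length != n_chromosomes")
        return tuple(self.chromosome_lengths)

    def to_yaml(self, path) -> None:
        d = dict(self.__dict__)
        d["chromosome_lengths"] = (
            list(self.lengths) if not isinstance(self.chromosome_lengths, int)
            else self.chromosome_lengths
        )
        if d["hotspot_spec"] is not None:
            d["hotspot_spec"] = [
                {"chromosome": c, "start": s, "end": e, "weight": w}
                for (c, s, e), w in d["hotspot_spec"]
            ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("hotspot_spec") is not None:
            d["hotspot_spec"] = [
                ((h["chromosome"], h["start"], h["end"]), h["weight"])
                for h in d["hotspot_spec"]
            ]
        if isinstance(d.get("chromosome_lengths"), list):
            d["chromosome_lengths"] = tuple(d["chromosome_lengths"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Sequence helpers

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    """i.i.d. DNA with the given GC fraction (A,C,G,T probabilities
    (1-gc)/2, gc/2, gc/2, (1-gc)/2)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cum = np.cumsum(p)
    u = rng.random(length)
    idx = np.searchsorted(cum, u, side="right").clip(0, 3)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def find_ta_positions(seq: str) -> np.ndarray:
    """0-based positions of the T of every (possibly overlapping) "TA"."""
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits = (a[:-1] == ord("T")) & (a[1:] == ord("A"))
    return np.flatnonzero(hits)


def sb100x_transposon(
    total_length: int = 32_400,
    end_length: int = 160,
    label: str = "SB100x",
    avoid_motif: str | None = None,
) -> TransposonModel:
    """Build a synthetic SB100x-style transposon of the given total length.

    The IR/DR ends are fixed pseudo-random sequences (deterministic across
    runs); ``avoid_motif`` (e.g. a restriction motif) is excluded from the
    ends by resampling.  Total lengths of 11_800 and 32_400 bp match the
    short- and long-cargo vectors the defaults describe.
    """
    if total_length < 2 * end_length + 100:
        raise ConfigurationError("total_length too short for the requested ends")
    rng = np.random.default_rng(zlib.crc32(f"sb100x-ends:{label}".encode()))

    def _end() -> str:
        for _ in range(100):
            s = _random_dna(rng, end_length, gc=0.5)
            if avoid_motif is None or (
                avoid_motif not in s and revcomp(avoid_motif) not in s
            ):
                return s
        raise ConfigurationError("could not sample a motif-free end sequence")

    left, right = _end(), _end()
    return TransposonModel(
        left_end=left,
        right_end=right,
        cargo_length=total_length - 2 * end_length,
        label=label,
    )


# ---------------------------------------------------------------------------
# Generators


def generate_genome(config: SimulationConfig) -> ReferenceGenome:
    """Simulate an i.i.d. multi-chromosome genome at the configured GC.

    Each chromosome is guaranteed to contain at least one TA dinucleotide
    (one is planted at a random interior position in the measure-zero case
    where none arose, e.g. at extreme GC).
    """
    chroms: dict[str, str] = {}
    for i, length in enumerate(config.lengths):
        if length <= 0:
            raise ConfigurationError("zero-length chromosome requested")
        if length < 10_000:
            raise ConfigurationError("chromosome lengths must be >= 10 kb")
        rng = _rng(config.seed, f"genome:{i}")
        seq = _random_dna(rng, length, config.gc_fraction)
        if "TA" not in seq:
            pos = int(rng.integers(0, length - 2))
            seq = seq[:pos] + "TA" + seq[pos + 2 :]
        chroms[f"chr{i + 1}"] = seq
    return ReferenceGenome(chroms)


def _gene_structure(rng: np.random.Generator, strand: str) -> dict:
    """Draw interval lengths for one gene (forward-coordinate layout)."""
    n_cds = int(rng.integers(1, 5))
    cds_lens = rng.integers(150, 401, size=n_cds).tolist()
    intron_lens = rng.integers(200, 1501, size=max(0, n_cds - 1)).tolist()
    utr5_len = int(rng.integers(100, 301)) if rng.random() < 0.9 else 0
    utr3_len = int(rng.integers(100, 401)) if rng.random() < 0.9 else 0
    return {
        "cds_lens": cds_lens,
        "intron_lens": intron_lens,
        "utr5_len": utr5_len,
        "utr3_len": utr3_len,
        "strand": strand,
    }


def _lay_out_gene(gene_id: str, chrom: str, start: int, st: dict) -> Gene:
    """Place drawn structure at ``start``; 5'UTR sits at the 5' end of the
    gene's own strand (left on +, right on -)."""
    strand = st["strand"]
    first_utr = st["utr5_len"] if strand == "+" else st["utr3_len"]
    last_utr = st["utr3_len"] if strand == "+" else st["utr5_len"]
    pos = start
    first_iv = None
    if first_utr:
        first_iv = (pos, pos + first_utr)
        pos += first_utr
    cds = []
    for i, clen in enumerate(st["cds_lens"]):
        cds.append((pos, pos + clen))
        pos += clen
        if i < len(st["intron_lens"]):
            pos += st["intron_lens"][i]
    last_iv = None
    if last_utr:
        last_iv = (pos, pos + last_utr)
        pos += last_utr
    end = pos
    if strand == "+":
        utr5 = [first_iv] if first_iv else []
        utr3 = [last_iv] if last_iv else []
    else:
        utr3 = [first_iv] if first_iv else []
        utr5 = [last_iv] if last_iv else []
    return Gene(gene_id, chrom, strand, start, end, cds, utr5, utr3)


def generate_gene_model(
    genome: ReferenceGenome,
    config: SimulationConfig,
    overlap_fraction: float = 0.0,
) -> GeneModel:
    """Place ``n_genes`` single-transcript genes, nonoverlapping by default.

    ``overlap_fraction`` > 0 forces that fraction of genes to be placed
    overlapping a previously placed gene, for category-precedence testing.
    """
    rng = _rng(config.seed, "genes")
    names = genome.names
    lengths = np.array([len(genome.chromosomes[n]) for n in names], dtype=float)
    probs = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    genes: list[Gene] = []
    for gi in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        st = _gene_structure(rng, strand)
        span = (
            st["utr5_len"]
            + st["utr3_len"]
            + sum(st["cds_lens"])
            + sum(st["intron_lens"])
        )
        force_overlap = overlap_fraction > 0 and genes and rng.random() < overlap_fraction
        done = False
        for _ in range(200):
            ci = int(rng.choice(len(names), p=probs))
            chrom = names[ci]
            limit = len(genome.chromosomes[chrom]) - span
            if limit <= 0:
                continue
            if force_overlap:
                host = genes[int(rng.integers(0, len(genes)))]
                limit_h = min(host.end - 1, len(genome.chromosomes[host.chromosome]) - span)
                if limit_h <= host.start - span + 1:
                    continue
                chrom = host.chromosome
                start = int(rng.integers(max(0, host.start - span + 1), limit_h))
            else:
                start = int(rng.integers(0, limit))
                if any(start < e and start + span > s for s, e in placed[chrom]):
                    continue
            genes.append(_lay_out_gene(f"gene{gi + 1:04d}", chrom, start, st))
            placed[chrom].append((start, start + span))
            done = True
            break
        if not done:
            raise PlacementError(
                f"could not place gene {gi + 1} of {config.n_genes} without overlap: "
                "gene density too high for the genome size"
            )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return GeneModel(genes)


def simulate_integrations(
    genome: ReferenceGenome,
    n: int,
    hotspot_spec: list[tuple[tuple[str, int, int], float]] | None = None,
    seed: int = 0,
) -> list[IntegrationEvent]:
    """Sample ``n`` distinct TA target sites, uniformly or with hotspots.

    Under the null every TA site is equally likely; a hotspot multiplies the
    sampling weight of every TA inside its window.  Sampling is without
    replacement (weighted, via Gumbel-top-k), so no two events share a site;
    orientation is a fair coin.
    """
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    rng = _rng(seed, "integrations")
    chrom_arr: list[str] = []
    pos_list: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for name, seq in genome.chromosomes.items():
        pos = find_ta_positions(seq)
        w = np.ones(len(pos))
        if hotspot_spec:
            for (hchrom, hstart, hend), mult in hotspot_spec:
                if hchrom == name:
                    w[(pos >= hstart) & (pos < hend)] *= mult
        chrom_arr.extend([name] * len(pos))
        pos_list.append(pos)
        weights.append(w)
    all_pos = np.concatenate(pos_list) if pos_list else np.array([], dtype=int)
    all_w = np.concatenate(weights) if weights else np.array([])
    if n > len(all_pos):
        raise CapacityError(
            f"requested {n} integrations but genome has only {len(all_pos)} TA sites"
        )
    if n == 0:
        return []
    # weighted sampling without replacement: top-n of Gumbel(log w) keys
    keys = np.log(all_w) + rng.gumbel(size=len(all_w))
    chosen = np.argpartition(-keys, n - 1)[:n]
    chosen = chosen[np.argsort(-keys[chosen])]
    orient = rng.random(n) < 0.5
    events = []
    for i, idx in enumerate(chosen):
        events.append(
            IntegrationEvent(
                chromosome=chrom_arr[int(idx)],
                position=int(all_pos[int(idx)]),
                orientation="+" if orient[i] else "-",
                event_id=f"ev{i + 1:05d}",
            )
        )
    events.sort(key=lambda e: (e.chromosome, e.position))
    return events


def _oriented_ends(tp: TransposonModel, orientation: str) -> tuple[str, str, str]:
    """(left-junction insert end, cargo, right-junction insert end) as they
    appear on the forward strand of the integrated chromosome."""
    if orientation == "+":
        return tp.left_end, tp.cargo_sequence(), tp.right_end
    # minus orientation: the whole insert is reverse-complemented
    return revcomp(tp.right_end), revcomp(tp.cargo_sequence()), revcomp(tp.left_end)


def splice_integration(
    seq: str, position: int, left_end: str, cargo: str, right_end: str
) -> str:
    """Insert an IR/DR-flanked cargo at a TA, duplicating the target site.

    Returns ``seq[:position+2] + left_end + cargo + right_end +
    seq[position:]`` — TA flanks both junctions, and the result is longer
    than the input by ``len(left_end) + len(cargo) + len(right_end) + 2``.
    """
    if position < 0 or position + 2 > len(seq) or seq[position : position + 2] != "TA":
        raise JunctionError(f"position {position} is not a TA dinucleotide")
    return seq[: position + 2] + left_end + cargo + right_end + seq[position:]


def construct_integrated_sequence(
    genome: ReferenceGenome, event: IntegrationEvent, tp: TransposonModel
) -> str:
    """Forward-strand sequence of the event's chromosome after integration.

    SB100x duplicates the target TA, so the result is
    ``genome[:position+2] + insert + genome[position:]`` — TA flanks both
    IR/DR junctions.  Minus orientation reverse-complements the insert.
    """
    seq = genome.chromosomes.get(event.chromosome)
    if seq is None:
        raise JunctionError(f"unknown chromosome {event.chromosome!r}")
    left, cargo, right = _oriented_ends(tp, event.orientation)
    return splice_integration(seq, event.position, left, cargo, right)


def _apply_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hit) == 0:
        return seq
    # replace each hit base with one of the three other bases
    idx_of = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        idx_of[b] = i
    cur = idx_of[arr[hit]]
    shift = rng.integers(1, 4, size=len(hit))
    arr[hit] = _BASE_BYTES[(cur + shift) % 4]
    return arr.tobytes().decode("ascii")


def generate_junction_reads(
    genome: ReferenceGenome,
    events: Sequence[IntegrationEvent],
    tp: TransposonModel,
    config: SimulationConfig,
) -> list[FastqRead]:
    """LAM-PCR-style junction reads for every event, both junctions.

    Each read starts with the terminal ``end_match_length`` bases of an
    IR/DR end (as read outward across the junction) followed by the
    adjacent genomic sequence, to ``read_length`` total.  Left-junction
    reads run on the minus strand of the reference, right-junction reads on
    the plus strand; both traverse the duplicated TA.  Substitution errors
    are i.i.d.; qualities are constant "I".  Events too close to a
    chromosome end yield truncated reads flagged ``|trunc`` in the name.
    """
    m = config.end_match_length
    if m < 15:
        raise ConfigurationError("end_match_length must be >= 15")
    if config.read_length <= m + 20:
        raise ConfigurationError("read_length must exceed end_match_length + 20")
    tp.check_against_genome(genome)
    g = config.read_length - m
    rng = _rng(config.seed, "reads")
    reads: list[FastqRead] = []
    for ev in events:
        seq = genome.chromosomes[ev.chromosome]
        p = ev.position
        left_ins, _, right_ins = _oriented_ends(tp, ev.orientation)
        for side in ("left", "right"):
            if side == "left":
                flank = seq[max(0, p + 2 - g) : p + 2]
                core = revcomp(left_ins[:m]) + revcomp(flank)
            else:
                flank = seq[p : p + g]
                core = right_ins[-m:] + flank
            truncated = len(flank) < g
            for k in range(config.reads_per_event):
                out = _apply_substitutions(rng, core, config.substitution_error_rate)
                name = f"{ev.event_id}|{side}|{k + 1}" + ("|trunc" if truncated else "")
                reads.append(FastqRead(name, out, "I" * len(out)))
    return reads


def generate_random_ta_fragments(
    genome: ReferenceGenome,
    n: int,
    fragment_length: int = 60,
    seed: int = 0,
) -> list[FastqRead]:
    """Uniformly sampled genomic fragments each containing at least one TA.

    These emulate the randomized control: random reference sequences
    containing TA, to be mapped and used as the null site set.
    """
    if fragment_length < 20:
        raise ConfigurationError("fragment_length must be >= 20")
    rng = _rng(seed, "ta-fragments")
    names = genome.names
    starts_avail = np.array(
        [max(0, len(genome.chromosomes[c]) - fragment_length + 1) for c in names],
        dtype=float,
    )
    if starts_avail.sum() == 0:
        raise CapacityError("no chromosome long enough for the fragment length")
    probs = starts_avail / starts_avail.sum()
    out: list[FastqRead] = []
    attempts = 0
    max_attempts = max(1000, 1000 * n)
    while len(out) < n:
        if attempts >= max_attempts:
            raise CapacityError(
                "could not find enough TA-containing fragments "
                f"(found {len(out)} of {n})"
            )
        attempts += 1
        ci = int(rng.choice(len(names), p=probs))
        chrom = names[ci]
        start = int(rng.integers(0, int(starts_avail[ci])))
        frag = genome.chromosomes[chrom][start : start + fragment_length]
        if "TA" in frag:
            out.append(FastqRead(f"rf{len(out) + 1:06d}", frag, "I" * len(frag)))
    return out


# ---------------------------------------------------------------------------
# GFF3 serialization (gene -> mRNA -> five_prime_UTR/CDS/three_prime_UTR)


def write_gff3(path, model: GeneModel, genome: ReferenceGenome | None = None,
               seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seed is not None:
            fh.write(f"#!seed {seed}\n")
        if genome is not None:
            for name, length in genome.lengths.items():
                fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in model.genes:
            base = f"{g.chromosome}\tprimsite\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(
                base + f"gene\t{g.start + 1}\t{g.end}" + tail +
                f".\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                base + f"mRNA\t{g.start + 1}\t{g.end}" + tail +
                f".\tID={mid};Parent={g.gene_id}\n"
            )
            parts = (
                [("five_prime_UTR", iv) for iv in g.utr5]
                + [("CDS", iv) for iv in g.cds]
                + [("three_prime_UTR", iv) for iv in g.utr3]
            )
            for ftype, (s, e) in sorted(parts, key=lambda t: t[1]):
                phase = "0" if ftype == "CDS" else "."
                fh.write(
                    base + f"{ftype}\t{s + 1}\t{e}" + tail +
                    f"{phase}\tParent={mid}\n"
                )


def read_gff3(path) -> GeneModel:
    """Parse a GFF3 written by :func:`write_gff3` back into a GeneModel."""
    genes: dict[str, Gene] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            s, e = int(start) - 1, int(end)
            ad = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = ad["ID"]
                genes[gid] = Gene(gid, chrom, strand, s, e, [], [], [])
            elif ftype == "mRNA":
                mrna_to_gene[ad["ID"]] = ad["Parent"]
            elif ftype in ("CDS", "five_prime_UTR", "three_prime_UTR"):
                gid = mrna_to_gene.get(ad["Parent"], ad["Parent"])
                g = genes[gid]
                if ftype == "CDS":
                    g.cds.append((s, e))
                elif ftype == "five_prime_UTR":
                    g.utr5.append((s, e))
                else:
                    g.utr3.append((s, e))
    out = sorted(genes.values(), key=lambda g: (g.chromosome, g.start))
    for g in out:
        g.cds.sort()
        g.utr5.sort()
        g.utr3.sort()
    return GeneModel(out)
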