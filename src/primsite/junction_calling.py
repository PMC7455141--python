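"""Recover unique integration sites from junction reads.

The pipeline per read: detect which IR/DR transposon end the read begins
with, trim it, map the remaining genomic fragment against both strands of
the reference (exact match, with a single-mismatch pigeonhole rescue),
convert the mapped coordinates to the canonical TA position, validate that
the reference dinucleotide there really is TA, then deduplicate calls into
a site table and summarize clonality.

Canonicalization: because SB100x duplicates the target TA, the left- and
right-junction reads of one event flank the same T index.  A fragment
mapping to the plus strand starts at the TA (T index = mapped start); a
fragment mapping to the minus strand ends at it (T index = start + len - 2).
Both junction reads of an event therefore merge to a single site.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import FastqRead, revcomp
from .synthetic_data import ReferenceGenome, TransposonModel

logger = logging.getLogger(__name__)

REJECT_REASONS = ("no_end", "ambiguous", "unmapped", "no_TA", "too_short")


@dataclass
class JunctionCall:
    read_id: str
    side: str | None = None
    trim_offset: int = 0
    chromosome: str | None = None
    position: int | None = None
    orientation: str | None = None
    mapped: bool = False
    reject_reason: str | None = None


@dataclass
class CallParams:
    """Tunables of the calling pipeline.

    ``merge_window`` > 0 would merge sites within that many bp; the default
    0 deduplicates on the exact TA position.
    """

    end_match_length: int = 20
    max_mismatches: int = 1
    min_fragment_length: int = 20
    merge_window: int = 0
    rescue_mismatch: bool = True


@dataclass
class MapResult:
    status: str  # mapped | ambiguous | unmapped | too_short
    chromosome: str | None = None
    start: int | None = None
    strand: str | None = None
    mismatches: int = 0


@dataclass
class CallResult:
    sites: pd.DataFrame
    rejections: Counter
    n_reads: int

    @property
    def n_mapped(self) -> int:
        return self.n_reads - sum(self.rejections.values())


@dataclass
class ClonalitySummary:
    max_clone_fraction: float
    shannon_entropy: float
    site_count: int


# ---------------------------------------------------------------------------
# End detection


def end_signatures(tp: TransposonModel, end_match_length: int) -> dict[str, str]:
    """Junction-proximal read prefixes: a left-junction read (minus-strand
    readout) begins with revcomp of the first bases of the left end; a
    right-junction read begins with the last bases of the right end."""
    m = end_match_length
    return {"left": revcomp(tp.left_end[:m]), "right": tp.right_end[-m:]}


def _mismatches(a: str, b: str, limit: int | None = None) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if limit is not None and n > limit:
                return n
    return n


def detect_transposon_end(
    read: str,
    tp: TransposonModel,
    end_match_length: int = 20,
    max_mismatches: int = 1,
) -> tuple[str, int] | None:
    """Which IR/DR end does the read begin with?

    Returns ``(side, trim_offset)`` for the side whose terminal
    ``end_match_length`` bases match the read prefix with at most
    ``max_mismatches`` substitutions, or None when neither matches.  Ties
    break toward fewer mismatches, then left.

    Raises ValueError for reads shorter than the signature (too_short).
    """
    if end_match_length < 15:
        raise ValueError("end_match_length must be >= 15")
    m = end_match_length
    if len(read) < m:
        raise ValueError("read shorter than end_match_length")
    prefix = read[:m]
    sigs = end_signatures(tp, m)
    best: tuple[int, str] | None = None
    for side in ("left", "right"):
        mm = _mismatches(prefix, sigs[side], limit=max_mismatches)
        if mm <= max_mismatches and (best is None or mm < best[0]):
            best = (mm, side)
    if best is None:
        return None
    return best[1], m


# ---------------------------------------------------------------------------
# Mapping


def _find_all(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _rescue_candidates(
    seq: str, frag: str, max_hits: int = 4
) -> list[tuple[int, int]]:
    """Positions where ``frag`` occurs in ``seq`` with exactly one mismatch,
    found by the pigeonhole principle (one half must match exactly)."""
    L = len(frag)
    half = L // 2
    seen: dict[int, int] = {}
    for offset, piece in ((0, frag[:half]), (half, frag[half:])):
        for hit in _find_all(seq, piece):
            start = hit - offset
            if start < 0 or start + L > len(seq) or start in seen:
                continue
            mm = _mismatches(seq[start : start + L], frag, limit=1)
            if mm == 1:
                seen[start] = mm
                if len(seen) >= max_hits:
                    return sorted(seen.items())
    return sorted(seen.items())


def map_genomic_fragment(
    fragment: str,
    genome: ReferenceGenome,
    min_length: int = 20,
    rescue_mismatch: bool = True,
) -> MapResult:
    """Locate a trimmed genomic fragment on either strand of the reference.

    Exactly one exact occurrence -> mapped; two or more -> ambiguous; zero
    -> one round of single-mismatch rescue, else unmapped.  A minus-strand
    hit is reported with the forward-strand start of the matched interval.
    """
    if len(fragment) < min_length:
        return MapResult("too_short")
    rc = revcomp(fragment)
    hits: list[tuple[str, int, str, int]] = []
    for name, seq in genome.chromosomes.items():
        for start in _find_all(seq, fragment):
            hits.append((name, start, "+", 0))
        for start in _find_all(seq, rc):
            hits.append((name, start, "-", 0))
        if len(hits) > 1:
            return MapResult("ambiguous")
    if len(hits) == 1:
        name, start, strand, mm = hits[0]
        return MapResult("mapped", name, start, strand, mm)
    if not rescue_mismatch:
        return MapResult("unmapped")
    for name, seq in genome.chromosomes.items():
        for start, mm in _rescue_candidates(seq, fragment):
            hits.append((name, start, "+", mm))
        for start, mm in _rescue_candidates(seq, rc):
            hits.append((name, start, "-", mm))
        if len(hits) > 1:
            return MapResult("ambiguous")
    if len(hits) == 1:
        name, start, strand, mm = hits[0]
        return MapResult("mapped", name, start, strand, mm)
    return MapResult("unmapped")


# ---------------------------------------------------------------------------
# TA canonicalization and validation


def canonical_ta_position(start: int, fragment_length: int, strand: str) -> int:
    """T index of the junction TA implied by a mapped fragment.

    Plus-strand fragments begin at the TA; minus-strand fragments end at it.
    """
    return start if strand == "+" else start + fragment_length - 2


def infer_orientation(side: str, strand: str) -> str:
    """Transposon orientation from detected end and mapped strand."""
    return "+" if (side, strand) in (("right", "+"), ("left", "-")) else "-"


def validate_ta_junction(call: JunctionCall, genome: ReferenceGenome) -> bool:
    """True iff the reference dinucleotide at the call's position is TA."""
    if not call.mapped or call.chromosome is None or call.position is None:
        return False
    seq = genome.chromosomes.get(call.chromosome)
    if seq is None:
        return False
    p = call.position
    if p < 0 or p + 2 > len(seq):
        return False
    return seq[p : p + 2] == "TA"


# ---------------------------------------------------------------------------
# Full per-read pipeline and deduplication


def _call_read(
    read: FastqRead,
    tp: TransposonModel,
    genome: ReferenceGenome,
    params: CallParams,
    map_cache: dict[str, MapResult],
) -> JunctionCall:
    call = JunctionCall(read_id=read.name)
    m = params.end_match_length
    if len(read.sequence) < m:
        call.reject_reason = "too_short"
        return call
    det = detect_transposon_end(read.sequence, tp, m, params.max_mismatches)
    if det is None:
        call.reject_reason = "no_end"
        return call
    call.side, call.trim_offset = det
    fragment = read.sequence[call.trim_offset :]
    if len(fragment) < params.min_fragment_length:
        call.reject_reason = "too_short"
        return call
    res = map_cache.get(fragment)
    if res is None:
        res = map_genomic_fragment(
            fragment, genome, params.min_fragment_length, params.rescue_mismatch
        )
        map_cache[fragment] = res
    if res.status != "mapped":
        call.reject_reason = res.status if res.status != "too_short" else "too_short"
        return call
    call.chromosome = res.chromosome
    call.position = canonical_ta_position(res.start, len(fragment), res.strand)
    call.orientation = infer_orientation(call.side, res.strand)
    call.mapped = True
    if not validate_ta_junction(call, genome):
        call.mapped = False
        call.chromosome = call.position = call.orientation = None
        call.reject_reason = "no_TA"
    return call


def call_unique_sites(
    reads: Iterable[FastqRead],
    tp: TransposonModel,
    genome: ReferenceGenome,
    params: CallParams | None = None,
    sample_id: str = "sample",
) -> CallResult:
    """Detect, trim, map, validate and deduplicate junction reads.

    Calls sharing (chromosome, TA position) merge into one unique site with
    ``support_reads`` contributing reads; orientation conflicts at one
    position keep the majority vote (tie -> "+", with a warning).  An empty
    surviving set yields an empty table plus a warning, not an error.
    """
    params = params or CallParams()
    rejections: Counter = Counter()
    per_site: dict[tuple[str, int], list[str]] = {}
    n_reads = 0
    map_cache: dict[str, MapResult] = {}
    for read in reads:
        n_reads += 1
        call = _call_read(read, tp, genome, params, map_cache)
        if not call.mapped:
            rejections[call.reject_reason] += 1
            continue
        per_site.setdefault((call.chromosome, call.position), []).append(
            call.orientation
        )
    rows = []
    for i, ((chrom, pos), orients) in enumerate(
        sorted(per_site.items()), start=1
    ):
        c = Counter(orients)
        if len(c) > 1:
            logger.warning(
                "orientation conflict at %s:%d (%s); keeping majority", chrom, pos, dict(c)
            )
        if c.get("+", 0) == c.get("-", 0):
            orientation = "+"
        else:
            orientation = c.most_common(1)[0][0]
        rows.append(
            {
                "chromosome": chrom,
                "position": pos,
                "orientation": orientation,
                "support_reads": len(orients),
                "site_id": f"site{i:05d}",
                "sample_id": sample_id,
            }
        )
    sites = pd.DataFrame(
        rows,
        columns=["chromosome", "position", "orientation", "support_reads",
                 "site_id", "sample_id"],
    )
    if sites.empty:
        logger.warning("no junction reads survived calling; empty site table")
    else:
        sites = sites.sort_values(
            ["chromosome", "position"], kind="stable"
        ).reset_index(drop=True)
    assert n_reads == int(sites["support_reads"].sum() if not sites.empty else 0) + sum(
        rejections.values()
    ), "rejection accounting must balance"
    return CallResult(sites=sites, rejections=rejections, n_reads=n_reads)


def map_random_fragments(
    fragments: Iterable[FastqRead], genome: ReferenceGenome
) -> pd.DataFrame:
    """Map random TA-containing fragments into a null site table.

    Each uniquely mapping fragment contributes one site at the first TA it
    covers (forward reference coordinates); ambiguous/unmapped fragments
    are dropped, mirroring the handling of real junction reads.
    """
    per_site: dict[tuple[str, int], int] = {}
    for frag in fragments:
        res = map_genomic_fragment(frag.sequence, genome, rescue_mismatch=False)
        if res.status != "mapped":
            continue
        seq = genome.chromosomes[res.chromosome]
        span = seq[res.start : res.start + len(frag.sequence)]
        # TA is its own reverse complement, so the reference span contains a
        # TA regardless of mapped strand
        off = span.find("TA")
        if off == -1:
            continue
        key = (res.chromosome, res.start + off)
        per_site[key] = per_site.get(key, 0) + 1
    rows = [
        {
            "chromosome": c,
            "position": p,
            "orientation": "+",
            "support_reads": n,
            "site_id": f"rand{i:05d}",
            "sample_id": "random",
        }
        for i, ((c, p), n) in enumerate(sorted(per_site.items()), start=1)
    ]
    return pd.DataFrame(
        rows,
        columns=["chromosome", "position", "orientation", "support_reads",
                 "site_id", "sample_id"],
    )


def compute_clonality(sites: pd.DataFrame) -> ClonalitySummary:
    """Clone-size summary from read support: the largest clone's fraction of
    all reads, Shannon entropy (nats) over clone fractions, and site count.

    Equal abundance of k sites gives entropy ln k; a single site gives
    (1.0, 0.0, 1).
    """
    if sites is None or sites.empty:
        raise ValueError("clonality is undefined for an empty site table")
    support = sites["support_reads"].to_numpy(dtype=float)
    if (support < 1).any():
        raise ValueError("support_reads must all be >= 1")
    frac = support / support.sum()
    entropy = float(-(frac * np.log(frac)).sum())
    return ClonalitySummary(
        max_clone_fraction=float(frac.max()),
        shannon_entropy=entropy,
        site_count=int(len(support)),
    )
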