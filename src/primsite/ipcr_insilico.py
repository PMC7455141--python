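"""In-silico inverse PCR (iPCR) for transposon junction recovery.

Models the wet-lab procedure: genomic DNA carrying an integrated transposon
is digested with a restriction enzyme (SacI by default), the fragments are
religated under intramolecular conditions (each fragment circularizes), and
nested primer pairs anchored in the vector amplify around the circle across
the vector-genome junction.  The amplicon is then searched for the IR/DR
terminal segment, the adjoining genomic run is mapped, and the TA junction
is validated, recovering the integration site.

Only intramolecular ligation is modeled (no concatemers), primer annealing
is exact after removing the 16 bp cloning tails, and no thermodynamics or
cycle kinetics are simulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .io import revcomp
from .junction_calling import canonical_ta_position, map_genomic_fragment
from .synthetic_data import (
    ConfigurationError,
    IntegrationEvent,
    JunctionError,
    ReferenceGenome,
    TransposonModel,
    construct_integrated_sequence,
    sb100x_transposon,
    _random_dna,
)

__all__ = [
    "RestrictionSpec",
    "PrimerPair",
    "IPCRProduct",
    "SACI",
    "AmbiguousProductError",
    "StructureError",
    "load_primer_pairs",
    "digest",
    "religate_and_amplify",
    "extract_ipcr_junction",
    "build_ipcr_ready_transposon",
    "recover_events_by_ipcr",
    "IPCRRecovery",
]


class AmbiguousProductError(RuntimeError):
    """A primer anneals more than once on a circle, or the genomic side of
    an amplicon maps to more than one locus."""


class StructureError(ValueError):
    """An amplicon lacks the expected IR/DR / genomic architecture."""


@dataclass(frozen=True)
class RestrictionSpec:
    """A restriction enzyme as motif plus cut offset within the motif.

    Overhang chemistry is not modeled: intramolecular religation restores
    the site regardless of where the offset splits the motif.
    """

    enzyme_name: str
    recognition_motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if set(self.recognition_motif) - set("ACGT"):
            raise ConfigurationError("recognition motif must be over ACGT")
        if not (0 <= self.cut_offset <= len(self.recognition_motif)):
            raise ConfigurationError("cut_offset must lie within the motif")


#: SacI: GAGCT^C
SACI = RestrictionSpec("SacI", "GAGCTC", 5)


@dataclass(frozen=True)
class PrimerPair:
    """A nested-PCR primer pair; the 5' ``tail_length`` bases of each primer
    are a cloning tail ignored during annealing."""

    name: str
    forward: str
    reverse: str
    tail_length: int = 16

    def __post_init__(self) -> None:
        for core in (self.forward_core, self.reverse_core):
            if len(core) < 18:
                raise ConfigurationError(
                    f"primer core of pair {self.name!r} shorter than 18 bp"
                )

    @property
    def forward_core(self) -> str:
        return self.forward.upper()[self.tail_length :]

    @property
    def reverse_core(self) -> str:
        return self.reverse.upper()[self.tail_length :]


@dataclass
class IPCRProduct:
    """One predicted inverse-PCR amplicon.

    The amplicon contains the (inner, for nested runs) forward primer core
    and the reverse complement of the reverse core exactly once each, in
    that order; ``junction`` is filled by :func:`extract_ipcr_junction`.
    """

    sequence: str
    length: int
    primer_pair: str
    junction: tuple[str, int] | None = None
    fragment_index: int = -1


def load_primer_pairs(path=None) -> list[PrimerPair]:
    """Load primer pairs from YAML; defaults to the packaged nested sets
    (EF1a p1/p2 and 3'HS1 p1/p2)."""
    if path is None:
        text = (
            resources.files("primsite").joinpath("data/primers.yaml").read_text()
        )
        doc = yaml.safe_load(text)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    return [
        PrimerPair(
            name=p["name"],
            forward=p["forward"],
            reverse=p["reverse"],
            tail_length=int(p.get("tail_length", 16)),
        )
        for p in doc["primer_pairs"]
    ]


def default_nested_groups(
    pairs: Sequence[PrimerPair] | None = None,
) -> list[tuple[PrimerPair, PrimerPair]]:
    """Group pairs into (outer p1, inner p2) nested couples by name order."""
    pairs = list(pairs) if pairs is not None else load_primer_pairs()
    if len(pairs) % 2:
        raise ConfigurationError("nested grouping needs an even number of pairs")
    return [(pairs[i], pairs[i + 1]) for i in range(0, len(pairs), 2)]


# ---------------------------------------------------------------------------
# Digestion


def digest(
    sequence: str, spec: RestrictionSpec, topology: str = "linear"
) -> list[str]:
    """Cut at every motif occurrence at ``cut_offset``.

    Linear topology yields k+1 fragments for k sites (possibly empty end
    fragments when a cut falls on a boundary); circular topology yields k
    fragments, or the whole molecule when k = 0.  Fragment order preserves
    input order.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    motif = spec.recognition_motif
    L = len(sequence)
    if topology == "linear":
        cuts = []
        i = sequence.find(motif)
        while i != -1:
            cuts.append(i + spec.cut_offset)
            i = sequence.find(motif, i + 1)
        frags = []
        prev = 0
        for c in cuts:
            frags.append(sequence[prev:c])
            prev = c
        frags.append(sequence[prev:])
        return frags
    if topology == "circular":
        doubled = sequence + sequence
        cuts = []
        i = doubled.find(motif)
        while i != -1 and i < L:
            cuts.append((i + spec.cut_offset) % L)
            i = doubled.find(motif, i + 1)
        cuts = sorted(set(cuts))
        if not cuts:
            return [sequence]
        frags = []
        for j, c in enumerate(cuts):
            nxt = cuts[(j + 1) % len(cuts)]
            arc = (nxt - c) % L
            if arc == 0:
                arc = L
            frags.append(doubled[c : c + arc])
        return frags
    raise ValueError(f"unknown topology {topology!r}")


# ---------------------------------------------------------------------------
# Religation + amplification


def _circle_find(circle: str, needle: str) -> list[int]:
    """Start offsets (mod circle length) of ``needle`` on a circular
    template, forward strand only."""
    L = len(circle)
    if len(needle) > L:
        return []
    doubled = circle + circle[: len(needle) - 1]
    out = []
    i = doubled.find(needle)
    while i != -1 and i < L:
        out.append(i)
        i = doubled.find(needle, i + 1)
    return out


def _amplify_circle(circle: str, pair: PrimerPair) -> str | None:
    """Amplicon of one primer pair on one circle, or None.

    Success requires the forward core and the reverse complement of the
    reverse core each to anneal exactly once with compatible orientation;
    the product is the arc from the forward-primer start to the
    reverse-primer end.  A primer annealing more than once raises
    AmbiguousProductError.
    """
    fwd = pair.forward_core
    rev_rc = revcomp(pair.reverse_core)
    for template in (circle, revcomp(circle)):
        f_hits = _circle_find(template, fwd)
        r_hits = _circle_find(template, rev_rc)
        if len(f_hits) > 1 or len(r_hits) > 1:
            raise AmbiguousProductError(
                f"primer of pair {pair.name!r} anneals more than once on a circle"
            )
        if len(f_hits) == 1 and len(r_hits) == 1:
            L = len(template)
            f = f_hits[0]
            rend = r_hits[0] + len(rev_rc)
            arc = (rend - f) % L
            if arc == 0:
                arc = L
            doubled = template + template
            return doubled[f : f + arc]
    return None


def _amplify_linear(template: str, pair: PrimerPair) -> str | None:
    """Nested reamplification inside a linear first-round product."""
    fwd = pair.forward_core
    rev_rc = revcomp(pair.reverse_core)
    f_hits = [i for i in _find_all_linear(template, fwd)]
    r_hits = [i for i in _find_all_linear(template, rev_rc)]
    if len(f_hits) > 1 or len(r_hits) > 1:
        raise AmbiguousProductError(
            f"primer of pair {pair.name!r} anneals more than once in a product"
        )
    if len(f_hits) == 1 and len(r_hits) == 1:
        f = f_hits[0]
        rend = r_hits[0] + len(rev_rc)
        if rend > f:
            return template[f:rend]
    return None


def _find_all_linear(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def religate_and_amplify(
    fragments: Sequence[str],
    pairs: Sequence[PrimerPair] | Sequence[tuple[PrimerPair, PrimerPair]],
    nested: bool = False,
    on_ambiguous: str = "raise",
) -> list[IPCRProduct]:
    """Circularize every fragment and predict nested-PCR amplicons.

    With ``nested=True``, ``pairs`` is a sequence of (outer, inner) couples
    and a product is reported only when the inner pair amplifies within the
    outer first-round product.  ``on_ambiguous`` is "raise" (default) or
    "skip" for fragments where a primer anneals more than once.
    """
    if not pairs:
        raise ValueError("at least one primer pair is required")
    if nested:
        groups = list(pairs)
    else:
        groups = [(p, None) for p in pairs]
    products: list[IPCRProduct] = []
    for idx, frag in enumerate(fragments):
        if not frag:
            continue
        for outer, inner in groups:
            try:
                prod = _amplify_circle(frag, outer)
                if prod is not None and inner is not None:
                    prod = _amplify_linear(prod, inner)
            except AmbiguousProductError:
                if on_ambiguous == "raise":
                    raise
                continue
            if prod is not None:
                name = inner.name if inner is not None else outer.name
                products.append(
                    IPCRProduct(
                        sequence=prod,
                        length=len(prod),
                        primer_pair=name,
                        fragment_index=idx,
                    )
                )
    return products


# ---------------------------------------------------------------------------
# Junction extraction


def extract_ipcr_junction(
    product: IPCRProduct,
    tp: TransposonModel,
    genome: ReferenceGenome,
    probe_length: int = 20,
    flank_length: int = 40,
    min_genomic: int = 20,
) -> IntegrationEvent:
    """Locate the IR/DR edge inside an amplicon and map the genomic side.

    The amplicon is scanned for the junction-proximal terminal segment of
    either transposon end (both strands); the adjoining genomic run is
    mapped with the junction caller's mapper and the TA junction validated.
    Raises StructureError when no IR/DR segment (or no mappable genomic
    run) is present, AmbiguousProductError when the genomic side is
    ambiguous, JunctionError when the junction dinucleotide is not TA.
    """
    seq = product.sequence
    L5 = tp.left_end[:probe_length]
    R3 = tp.right_end[-probe_length:]
    # (signature, genomic side relative to the hit, orientation when the
    # genomic run maps to the forward strand)
    cases = [
        (L5, "before", "+"),
        (R3, "after", "+"),
        (revcomp(R3), "before", "-"),
        (revcomp(L5), "after", "-"),
    ]
    candidates: list[tuple[str, int, str]] = []
    found_signature = False
    for sig, where, orient_plus in cases:
        for i in _find_all_linear(seq, sig):
            found_signature = True
            if where == "before":
                gfrag = seq[max(0, i - flank_length) : i]
            else:
                j = i + len(sig)
                gfrag = seq[j : j + flank_length]
            if len(gfrag) < min_genomic:
                continue
            res = map_genomic_fragment(gfrag, genome, min_length=min_genomic,
                                       rescue_mismatch=False)
            if res.status == "ambiguous":
                raise AmbiguousProductError("genomic side maps ambiguously")
            if res.status != "mapped":
                continue
            # the genomic run ends at the TA ("before") or begins at it
            # ("after"); canonical_ta_position handles the strand algebra
            # for the begins-at-TA geometry, the other is its mirror
            if where == "after":
                ta = canonical_ta_position(res.start, len(gfrag), res.strand)
            else:
                ta = canonical_ta_position(res.start, len(gfrag),
                                           "-" if res.strand == "+" else "+")
            orientation = orient_plus if res.strand == "+" else (
                "-" if orient_plus == "+" else "+"
            )
            candidates.append((res.chromosome, ta, orientation))
    if not candidates:
        raise StructureError(
            "no IR/DR segment with a mappable genomic side in amplicon"
        )
    uniq = sorted(set(candidates))
    if len(uniq) > 1:
        raise AmbiguousProductError(
            f"amplicon implies {len(uniq)} distinct junctions"
        )
    chrom, ta, orientation = uniq[0]
    ref = genome.chromosomes[chrom]
    if ta < 0 or ta + 2 > len(ref) or ref[ta : ta + 2] != "TA":
        raise JunctionError(
            f"junction dinucleotide at {chrom}:{ta} is not TA"
        )
    product.junction = (chrom, ta)
    return IntegrationEvent(
        chromosome=chrom,
        position=ta,
        orientation=orientation,
        event_id=f"ipcr:{product.primer_pair}:{product.fragment_index}",
    )


# ---------------------------------------------------------------------------
# iPCR-ready transposon and end-to-end recovery


def _motif_free_dna(rng: np.random.Generator, length: int, motif: str) -> str:
    for _ in range(100):
        s = _random_dna(rng, length, gc=0.5)
        if motif not in s and revcomp(s).find(motif) == -1:
            return s
    raise ConfigurationError("could not sample motif-free spacer")


def build_ipcr_ready_transposon(
    total_length: int = 32_400,
    primer_pairs: Sequence[PrimerPair] | None = None,
    spec: RestrictionSpec = SACI,
    end_length: int = 160,
    spacer_length: int = 30,
    label: str = "SB100x-iPCR",
) -> TransposonModel:
    """A transposon whose cargo embeds nested iPCR primer cassettes.

    Near the left end the cargo carries the first nested group's primer
    sites followed by a restriction site, mirrored for the second group
    near the right end, so that digestion of the integrated locus releases
    junction fragments on which nested PCR amplifies across each junction
    into flanking genomic DNA — the geometry the printed primer sets were
    designed for.
    """
    groups = default_nested_groups(primer_pairs)
    if len(groups) < 2:
        raise ConfigurationError("need two nested groups (left and right)")
    (p1, p2), (q1, q2) = groups[0], groups[1]
    motif = spec.recognition_motif
    for pair in (p1, p2, q1, q2):
        for core in (pair.forward_core, pair.reverse_core):
            if motif in core or motif in revcomp(core):
                raise ConfigurationError(
                    f"primer core of {pair.name!r} contains the restriction motif"
                )
    rng = np.random.default_rng(zlib.crc32(f"ipcr-cassette:{label}".encode()))
    sp = lambda: _motif_free_dna(rng, spacer_length, motif)  # noqa: E731
    left_cassette = (
        revcomp(p2.reverse_core) + sp()
        + revcomp(p1.reverse_core) + sp()
        + p1.forward_core + sp()
        + p2.forward_core + sp()
        + motif
    )
    right_cassette = (
        motif + sp()
        + revcomp(q2.reverse_core) + sp()
        + revcomp(q1.reverse_core) + sp()
        + q1.forward_core + sp()
        + q2.forward_core + sp()
    )
    base = sb100x_transposon(
        total_length=total_length, end_length=end_length,
        label=label, avoid_motif=motif,
    )
    cargo_len = total_length - 2 * end_length
    middle_len = cargo_len - len(left_cassette) - len(right_cassette)
    if middle_len < 0:
        raise ConfigurationError("total_length too short for primer cassettes")
    middle = _random_dna(rng, middle_len, gc=0.5)
    cargo = left_cassette + middle + right_cassette
    return TransposonModel(
        left_end=base.left_end,
        right_end=base.right_end,
        cargo_length=cargo_len,
        label=label,
        cargo=cargo,
    )


@dataclass
class IPCRRecovery:
    """Outcome of end-to-end iPCR recovery over a set of events."""

    recovered: dict[str, IntegrationEvent] = field(default_factory=dict)
    unrecoverable: dict[str, str] = field(default_factory=dict)
    products: list[IPCRProduct] = field(default_factory=list)


def recover_events_by_ipcr(
    genome: ReferenceGenome,
    events: Sequence[IntegrationEvent],
    tp: TransposonModel,
    primer_pairs: Sequence[PrimerPair] | None = None,
    spec: RestrictionSpec = SACI,
    max_genomic_flank: int = 50_000,
) -> IPCRRecovery:
    """Digest/religate/amplify each integrated locus and extract junctions.

    ``max_genomic_flank`` caps the genomic window considered around each
    event (a proxy for the circle sizes PCR can traverse); events whose
    nearest restriction site lies beyond it, or whose fragments fail the
    primer geometry, are reported as unrecoverable, never mis-assigned.
    """
    groups = default_nested_groups(primer_pairs)
    out = IPCRRecovery()
    for ev in events:
        seq = genome.chromosomes[ev.chromosome]
        a = max(0, ev.position - max_genomic_flank)
        b = min(len(seq), ev.position + max_genomic_flank)
        whole = construct_integrated_sequence(
            ReferenceGenome({ev.chromosome: seq}), ev, tp
        )
        construct = whole[a : b + tp.total_length() + 2]
        frags = digest(construct, spec, topology="linear")
        # interior fragments only: the two terminal fragments are bounded by
        # the window edge, not by a real restriction site
        interior = frags[1:-1] if len(frags) > 2 else []
        try:
            products = religate_and_amplify(
                interior, groups, nested=True, on_ambiguous="skip"
            )
        except AmbiguousProductError:
            products = []
        hits = []
        for prod in products:
            try:
                rec = extract_ipcr_junction(prod, tp, genome)
            except (StructureError, AmbiguousProductError, JunctionError):
                continue
            out.products.append(prod)
            if rec.chromosome == ev.chromosome and rec.position == ev.position:
                hits.append(rec)
        if hits:
            out.recovered[ev.event_id] = IntegrationEvent(
                ev.chromosome, ev.position, hits[0].orientation, ev.event_id
            )
        else:
            out.unrecoverable[ev.event_id] = (
                "no junction-spanning amplicon within the fragment-size cap"
            )
    return out
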