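"""Splicing outcomes of minigene assays: events, products, consequences.

A :class:`MinigeneConstruct` models an exon-trap construct: two flanking
trap-vector exons and a genomic insert of gene exons and introns.  Observed
transcript products are described as sets of :class:`SpliceEvent`s relative
to the canonical product (empty event set).  Reconstruction is arithmetic
on event length deltas; when element sequences are supplied, the literal
product sequence is also assembled so premature termination codons can be
located by translation.

Event nomenclature
------------------
Labels follow the field's compact convention for minigene products:

* whole-exon skip                       ``ΔE<n>``
* full intron retention                 ``▼I<n>``
* partial loss at an exon's 5'/3' end   ``ΔE<n>p<k>`` / ``ΔE<n>q<k>``
* partial intron inclusion at 5'/3' end ``▼I<n>p<k>`` / ``▼I<n>q<k>``

Cryptic-site use at a junction is expressed through the equivalent partial
event: a donor shift into the intron by k nt is ``▼I<n>p<k>``; a donor
shift into the exon is ``ΔE<n>q<k>`` (mirrored for acceptors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .gene_model import TranscriptModel

EXON_SKIP = "exon_skip"
INTRON_RETENTION = "intron_retention"
PARTIAL_EXON_DEL = "partial_exon_del"
PARTIAL_INTRON_INCLUSION = "partial_intron_inclusion"
CRYPTIC_SITE_USE = "cryptic_site_use"

_KINDS = (
    EXON_SKIP,
    INTRON_RETENTION,
    PARTIAL_EXON_DEL,
    PARTIAL_INTRON_INCLUSION,
    CRYPTIC_SITE_USE,
)

CANONICAL = "canonical"
IN_FRAME_DEL = "in_frame_del"
IN_FRAME_INS = "in_frame_ins"
FRAMESHIFT = "frameshift"
NON_CODING = "non_coding"


class EventConflictError(ValueError):
    """Two events target the same construct element."""


class UnknownTargetError(KeyError):
    """An event references an element absent from the construct."""


@dataclass(frozen=True)
class MinigeneConstruct:
    """Exon-trap construct: vector exons flanking a genomic insert.

    ``insert_exons``/``insert_introns`` are ordered (id, length) pairs in
    transcript orientation; introns interleave the exons.  When the insert
    contains the gene's terminal exon (``contains_terminal_exon``), the 3'
    vector exon does not appear in the spliced product and is modeled with
    effective length 0.  Optional ``exon_seqs``/``intron_seqs`` supply
    literal sequences (same ids) for sequence-level reconstruction;
    ``vector5_seq``/``vector3_seq`` likewise.
    """

    insert_exons: tuple[tuple[str, int], ...]
    insert_introns: tuple[tuple[str, int], ...]
    vector_exon_5len: int = 120
    vector_exon_3len: int = 150
    contains_terminal_exon: bool = False
    exon_seqs: Optional[dict[str, str]] = None
    intron_seqs: Optional[dict[str, str]] = None
    vector5_seq: Optional[str] = None
    vector3_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.insert_introns) != len(self.insert_exons) - 1:
            raise ValueError("introns must interleave exons (one fewer)")
        for _, ln in self.insert_exons + self.insert_introns:
            if ln <= 0:
                raise ValueError("element lengths must be positive")
        if self.vector_exon_5len < 0 or self.vector_exon_3len < 0:
            raise ValueError("vector exon lengths must be non-negative")
        if self.exon_seqs is not None:
            for eid, ln in self.insert_exons:
                if len(self.exon_seqs[eid]) != ln:
                    raise ValueError(f"sequence length mismatch for exon {eid}")
        if self.intron_seqs is not None:
            for iid, ln in self.insert_introns:
                if len(self.intron_seqs[iid]) != ln:
                    raise ValueError(f"sequence length mismatch for intron {iid}")

    @property
    def effective_vector_3len(self) -> int:
        return 0 if self.contains_terminal_exon else self.vector_exon_3len

    @property
    def canonical_length(self) -> int:
        return (
            self.vector_exon_5len
            + sum(ln for _, ln in self.insert_exons)
            + self.effective_vector_3len
        )

    def element_length(self, target_id: str) -> int:
        for tid, ln in self.insert_exons + self.insert_introns:
            if tid == target_id:
                return ln
        raise UnknownTargetError(target_id)

    @property
    def has_sequences(self) -> bool:
        return self.exon_seqs is not None and self.intron_seqs is not None


@dataclass(frozen=True)
class SpliceEvent:
    """One deviation from canonical splicing of a construct element.

    ``boundary_shift_nt`` is the unsigned shift magnitude for partial /
    cryptic events and must be 0 for whole-element events.  ``side`` is
    'p' (5' end of the element) or 'q' (3' end) for partial events; for
    ``cryptic_site_use`` the target is an intron and ``side`` names the
    intron end whose sequence is included: see :func:`event_label`.
    """

    kind: str
    target_id: str
    boundary_shift_nt: int = 0
    side: Optional[str] = None  # 'p' | 'q'

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in (EXON_SKIP, INTRON_RETENTION):
            if self.boundary_shift_nt != 0:
                raise ValueError("whole-element events carry no boundary shift")
        else:
            if self.boundary_shift_nt <= 0:
                raise ValueError("partial/cryptic events need a positive shift")
            if self.side not in ("p", "q"):
                raise ValueError("partial/cryptic events need side 'p' or 'q'")

    def length_delta(self, construct: MinigeneConstruct) -> int:
        ln = construct.element_length(self.target_id)
        if self.kind == EXON_SKIP:
            return -ln
        if self.kind == INTRON_RETENTION:
            return ln
        if self.kind == PARTIAL_EXON_DEL:
            if self.boundary_shift_nt > ln:
                raise ValueError("partial deletion exceeds exon length")
            return -self.boundary_shift_nt
        if self.kind in (PARTIAL_INTRON_INCLUSION, CRYPTIC_SITE_USE):
            if self.boundary_shift_nt > ln:
                raise ValueError("inclusion exceeds intron length")
            return self.boundary_shift_nt
        raise AssertionError(self.kind)


def event_label(event: SpliceEvent) -> str:
    """Deterministic nomenclature string for one event (see module docs)."""
    n = event.target_id.lstrip("EI")
    if event.kind == EXON_SKIP:
        return f"ΔE{n}"
    if event.kind == INTRON_RETENTION:
        return f"▼I{n}"
    if event.kind == PARTIAL_EXON_DEL:
        return f"ΔE{n}{event.side}{event.boundary_shift_nt}"
    # partial intron inclusion and cryptic-site use at an intron end
    return f"▼I{n}{event.side}{event.boundary_shift_nt}"


@dataclass(frozen=True)
class TranscriptProduct:
    """One observed (or candidate) splicing product of a construct."""

    events: tuple[SpliceEvent, ...]
    length_nt: int
    net_cds_change_nt: int
    consequence: str
    ptc_codon: Optional[int] = None
    affected_domains: tuple[str, ...] = ()
    sequence: Optional[str] = None

    @property
    def is_canonical(self) -> bool:
        return not self.events

    @property
    def label(self) -> str:
        return "canonical" if self.is_canonical else "+".join(
            event_label(e) for e in self.events
        )


def reconstruct_product(
    construct: MinigeneConstruct, events: Sequence[SpliceEvent]
) -> TranscriptProduct:
    """Apply events to the canonical product; compute length and frame.

    Length is the canonical length plus the sum of signed event deltas.
    The net CDS change equals that sum (vector exons are untranslated
    trap sequence; all events target insert elements).  When the construct
    carries sequences the literal product sequence is assembled as well and
    any in-frame stop introduced by included intronic sequence is located
    by translation.
    """
    seen: set[str] = set()
    for e in events:
        construct.element_length(e.target_id)  # raises UnknownTargetError
        if e.target_id in seen:
            raise EventConflictError(
                f"multiple events target {e.target_id!r}"
            )
        seen.add(e.target_id)
    delta = sum(e.length_delta(construct) for e in events)
    length = construct.canonical_length + delta
    consequence = CANONICAL if not events else (
        FRAMESHIFT if delta % 3 != 0
        else (IN_FRAME_DEL if delta < 0 else IN_FRAME_INS if delta > 0 else CANONICAL)
    )
    # delta == 0 with events present (e.g. compensating partials): in-frame
    if events and delta == 0:
        consequence = IN_FRAME_DEL  # altered but frame-preserving product
    sequence = None
    ptc = None
    if construct.has_sequences:
        sequence = _assemble_sequence(construct, events)
        assert len(sequence) == length, "event arithmetic disagrees with sequence"
        if consequence in (IN_FRAME_INS, IN_FRAME_DEL) and delta != 0:
            ptc = _find_ptc(construct, sequence)
            # an in-frame inclusion carrying a stop codon truncates the protein
    return TranscriptProduct(
        events=tuple(events),
        length_nt=length,
        net_cds_change_nt=delta,
        consequence=consequence,
        ptc_codon=ptc,
        sequence=sequence,
    )


def _assemble_sequence(
    construct: MinigeneConstruct, events: Sequence[SpliceEvent]
) -> str:
    by_target = {e.target_id: e for e in events}
    parts = [construct.vector5_seq or "N" * construct.vector_exon_5len]
    exons = construct.insert_exons
    introns = construct.insert_introns
    for i, (eid, _) in enumerate(exons):
        seq = construct.exon_seqs[eid]
        ev = by_target.get(eid)
        if ev is not None:
            if ev.kind == EXON_SKIP:
                seq = ""
            elif ev.kind == PARTIAL_EXON_DEL:
                k = ev.boundary_shift_nt
                seq = seq[k:] if ev.side == "p" else seq[: len(seq) - k]
            else:
                raise EventConflictError(
                    f"event kind {ev.kind} cannot target exon {eid}"
                )
        parts.append(seq)
        if i < len(introns):
            iid, _ = introns[i]
            iev = by_target.get(iid)
            if iev is not None:
                iseq = construct.intron_seqs[iid]
                if iev.kind == INTRON_RETENTION:
                    parts.append(iseq)
                elif iev.kind in (PARTIAL_INTRON_INCLUSION, CRYPTIC_SITE_USE):
                    k = iev.boundary_shift_nt
                    parts.append(iseq[:k] if iev.side == "p" else iseq[-k:])
                else:
                    raise EventConflictError(
                        f"event kind {iev.kind} cannot target intron {iid}"
                    )
    parts.append(construct.vector3_seq or "N" * construct.effective_vector_3len)
    return "".join(parts)


def _find_ptc(construct: MinigeneConstruct, sequence: str) -> Optional[int]:
    """First stop codon in the insert reading frame, as a codon index.

    The insert CDS is assumed to start at the first insert base in frame 0
    (the synthetic generator and tests construct inserts that way).
    """
    cds = sequence[
        construct.vector_exon_5len : len(sequence) - construct.effective_vector_3len
    ]
    stops = {"TAA", "TAG", "TGA"}
    for i in range(0, len(cds) - 2, 3):
        if cds[i : i + 3] in stops:
            return i // 3 + 1
    return None


# ---------------------------------------------------------------------------
# protein-level consequence against the full transcript


@dataclass(frozen=True)
class Consequence:
    consequence: str
    ptc_codon: Optional[int]
    affected_domains: tuple[str, ...]
    hits_critical_domain: bool


def consequence_of(
    product: TranscriptProduct,
    transcript: TranscriptModel,
    exon_number_map: Optional[dict[str, int]] = None,
) -> Consequence:
    """Protein-level consequence of a product on the full transcript.

    ``exon_number_map`` maps construct element ids to 1-based transcript
    exon numbers (defaults to parsing trailing digits from ids like "E12"
    or "I12").  Affected domains are those overlapping removed codons for
    in-frame losses, inserted-at codons for in-frame gains, and every codon
    downstream of the first altered one for frameshifts.
    """
    if not product.events:
        return Consequence(CANONICAL, None, (), False)

    def exon_no(target_id: str) -> int:
        if exon_number_map and target_id in exon_number_map:
            return exon_number_map[target_id]
        digits = "".join(ch for ch in target_id if ch.isdigit())
        if not digits:
            raise UnknownTargetError(
                f"cannot infer exon number from id {target_id!r}"
            )
        return int(digits)

    codon_spans: list[tuple[int, int]] = []
    frameshift = product.net_cds_change_nt % 3 != 0
    for e in product.events:
        n = exon_no(e.target_id)
        if e.kind in (EXON_SKIP, PARTIAL_EXON_DEL):
            c1, c2 = transcript.exon_cdna_span(n - 1)
        else:  # intron events alter codons at/after the donor of exon n
            c1 = c2 = transcript.exon_cdna_ends[n - 1]
        # clip to CDS
        c1 = max(c1, transcript.cds_start_cdna)
        c2 = min(c2, transcript.cds_end_cdna)
        if c1 > c2:
            continue
        a1 = transcript.codon_of(c1)
        a2 = transcript.codon_of(c2)
        if frameshift:
            a2 = transcript.protein_length
        codon_spans.append((a1, a2))
    if not codon_spans:
        return Consequence(NON_CODING, None, (), False)
    affected = []
    hits_critical = False
    for d in transcript.domains:
        if any(a1 <= d.aa_end and d.aa_start <= a2 for a1, a2 in codon_spans):
            affected.append(d.name)
            hits_critical = hits_critical or d.critical
    consequence = FRAMESHIFT if frameshift else product.consequence
    return Consequence(consequence, product.ptc_codon, tuple(affected), hits_critical)
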