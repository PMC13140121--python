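"""Transcript models, HGVS c. parsing, and extended splice region windows.

This module is the coordinate backbone of the package.  A
:class:`TranscriptModel` holds the ordered exon structure of a transcript
(genomic intervals, 0-based half-open, in transcript orientation) together
with CDS bounds in cDNA space and a protein domain table.  On top of it sit

* a parser/formatter for the restricted HGVS cDNA grammar used for
  splice-region work (``c.6558+4A>G``, ``c.592+33_593-31del``,
  ``c.2075_2079delinsGTA``, ``dup``, ``ins``),
* centralized cDNA <-> genomic conversion (the only place in the package
  where 1-based HGVS coordinates meet 0-based genomic intervals), and
* computation of extended splice region windows: for every internal
  exon-exon junction, the last/first ``window_nt`` exonic nucleotides plus
  intronic offsets +-3..+-50, explicitly excluding the canonical +-1,2
  dinucleotides.

Conventions
-----------
Genomic intervals are 0-based half-open.  cDNA positions are 1-based.
Intronic positions are written as (anchor cDNA position, signed offset);
an offset of 0 means exonic.  Minus-strand transcripts are fully
supported; exon lists and all windows are expressed in transcript
orientation, so downstream code never branches on strand.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union


class HgvsParseError(ValueError):
    """Malformed HGVS syntax; the message names the offending token."""


class CoordinateError(ValueError):
    """A position falls outside the transcript or violates exon structure."""


class NonCodingError(CoordinateError):
    """A cDNA position lies outside the CDS."""


class TranscriptMismatchError(ValueError):
    """A variant was combined with a transcript it was not parsed against."""


# ---------------------------------------------------------------------------
# transcript model


@dataclass(frozen=True)
class Domain:
    """Protein domain interval, 1-based inclusive amino-acid coordinates."""

    name: str
    aa_start: int
    aa_end: int
    critical: bool = False


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure + CDS bounds + domain table for one transcript.

    ``exons`` are genomic intervals (0-based half-open) ordered 5'->3' in
    *transcript* orientation: ascending genomic start for ``+`` strand,
    descending for ``-``.
    """

    transcript_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_cdna: int
    cds_end_cdna: int
    domains: tuple[Domain, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        for g0, g1 in self.exons:
            if g1 <= g0:
                raise ValueError(f"empty or inverted exon interval ({g0}, {g1})")
        # non-overlap + transcript-orientation ordering
        ordered = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for (a0, a1), (b0, b1) in zip(ordered, ordered[1:]):
            if b0 < a1:
                raise ValueError("exons overlap or are not sorted 5'->3'")
        n = self.cdna_length
        if not (1 <= self.cds_start_cdna <= self.cds_end_cdna <= n):
            raise ValueError("CDS bounds outside transcript")
        if (self.cds_end_cdna - self.cds_start_cdna + 1) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        aa_len = self.protein_length
        for d in self.domains:
            if not (1 <= d.aa_start <= d.aa_end <= aa_len):
                raise ValueError(f"domain {d.name} outside protein (1..{aa_len})")

    # -- derived structure ------------------------------------------------

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(g1 - g0 for g0, g1 in self.exons)

    @property
    def cdna_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def protein_length(self) -> int:
        # excludes the stop codon
        return (self.cds_end_cdna - self.cds_start_cdna + 1) // 3 - 1

    @property
    def exon_cdna_ends(self) -> tuple[int, ...]:
        """1-based cDNA coordinate of the last base of each exon."""
        ends, total = [], 0
        for ln in self.exon_lengths:
            total += ln
            ends.append(total)
        return tuple(ends)

    def exon_cdna_span(self, exon_index: int) -> tuple[int, int]:
        """1-based inclusive cDNA span of exon ``exon_index`` (0-based index)."""
        ends = self.exon_cdna_ends
        start = 1 if exon_index == 0 else ends[exon_index - 1] + 1
        return start, ends[exon_index]

    def intron_length(self, intron_index: int) -> int:
        """Length of the intron following exon ``intron_index`` (0-based)."""
        a, b = self.exons[intron_index], self.exons[intron_index + 1]
        if self.strand == "+":
            return b[0] - a[1]
        return a[0] - b[1]

    def exon_index_of(self, pos: int) -> int:
        """Index of the exon containing 1-based cDNA position ``pos``."""
        if not 1 <= pos <= self.cdna_length:
            raise CoordinateError(
                f"cDNA position {pos} outside transcript 1..{self.cdna_length}"
            )
        for i, end in enumerate(self.exon_cdna_ends):
            if pos <= end:
                return i
        raise AssertionError("unreachable")

    # -- coordinate conversion -------------------------------------------

    def cdna_to_genomic(self, pos: int, offset: int = 0) -> int:
        """Map (cDNA position, intronic offset) to a 0-based genomic position.

        With ``offset == 0`` this is the exonic base itself; positive offsets
        walk into the downstream intron, negative into the upstream one,
        following transcript orientation (strand-aware).
        """
        i = self.exon_index_of(pos)
        start_c, end_c = self.exon_cdna_span(i)
        k = pos - start_c  # 0-based within exon, transcript orientation
        g0, g1 = self.exons[i]
        if self.strand == "+":
            g = g0 + k
        else:
            g = g1 - 1 - k
        if offset:
            if offset > 0 and pos != end_c:
                raise CoordinateError(
                    f"positive offset anchored at c.{pos}, which is not an exon end"
                )
            if offset < 0 and pos != start_c:
                raise CoordinateError(
                    f"negative offset anchored at c.{pos}, which is not an exon start"
                )
            if offset > 0 and i == len(self.exons) - 1:
                raise CoordinateError("offset past the terminal exon")
            if offset < 0 and i == 0:
                raise CoordinateError("offset before the first exon")
            intron_len = self.intron_length(i if offset > 0 else i - 1)
            if abs(offset) > intron_len:
                raise CoordinateError(
                    f"offset {offset:+d} exceeds intron length {intron_len}"
                )
            g = g + offset if self.strand == "+" else g - offset
        return g

    def genomic_to_cdna(self, g: int) -> tuple[int, int]:
        """Map a 0-based genomic position to (cDNA position, offset).

        Exonic positions return offset 0; intronic positions anchor to the
        nearer junction per HGVS convention (ties go to the upstream exon
        end).  Positions outside the transcript span raise CoordinateError.
        """
        for i, (g0, g1) in enumerate(self.exons):
            if g0 <= g < g1:
                start_c, _ = self.exon_cdna_span(i)
                k = g - g0 if self.strand == "+" else g1 - 1 - g
                return start_c + k, 0
        for i in range(len(self.exons) - 1):
            up_end_c = self.exon_cdna_ends[i]
            donor_g = self.cdna_to_genomic(up_end_c)
            acceptor_g = self.cdna_to_genomic(up_end_c + 1)
            if self.strand == "+":
                lo, hi = donor_g + 1, acceptor_g - 1
                if lo <= g <= hi:
                    d_don, d_acc = g - donor_g, acceptor_g - g
            else:
                lo, hi = acceptor_g + 1, donor_g - 1
                if lo <= g <= hi:
                    d_don, d_acc = donor_g - g, g - acceptor_g
                else:
                    continue
            if not lo <= g <= hi:
                continue
            if d_don <= d_acc:
                return up_end_c, d_don
            return up_end_c + 1, -d_acc
        raise CoordinateError(f"genomic position {g} outside transcript span")

    # -- protein mapping --------------------------------------------------

    def codon_of(self, pos: int) -> int:
        if pos < self.cds_start_cdna or pos > self.cds_end_cdna:
            raise NonCodingError(f"c.{pos} is non-coding for {self.transcript_id}")
        return (pos - self.cds_start_cdna) // 3 + 1

    def domain_at(self, codon: int) -> Optional[Domain]:
        for d in self.domains:
            if d.aa_start <= codon <= d.aa_end:
                return d
        return None


def map_cdna_to_protein(
    pos: int, transcript: TranscriptModel
) -> tuple[int, Optional[Domain]]:
    """Codon index (1-based) and containing domain (or None) of a CDS position."""
    codon = transcript.codon_of(pos)
    return codon, transcript.domain_at(codon)


# ---------------------------------------------------------------------------
# HGVS c. variants

SUBSTITUTION = "substitution"
DELETION = "deletion"
DELINS = "delins"
DUPLICATION = "duplication"
INSERTION = "insertion"

_EDIT_KINDS = (SUBSTITUTION, DELETION, DELINS, DUPLICATION, INSERTION)


@dataclass(frozen=True)
class CVariant:
    """A parsed HGVS cDNA variant anchored to one transcript.

    ``start_offset``/``end_offset`` of 0 denote exonic positions.  For
    single-position variants start == end.
    """

    transcript_id: str
    start_pos: int
    start_offset: int
    end_pos: int
    end_offset: int
    edit: str
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.edit not in _EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.edit!r}")
        if (self.start_pos, self.start_offset) > (self.end_pos, self.end_offset):
            raise ValueError("variant range start follows its end")

    @property
    def is_range(self) -> bool:
        return (self.start_pos, self.start_offset) != (self.end_pos, self.end_offset)

    @property
    def is_intronic(self) -> bool:
        return self.start_offset != 0 or self.end_offset != 0


_HYPHENS = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")

_POS = re.compile(r"(?P<pos>\d+)(?P<off>[+-]\d+)?")
_HGVS = re.compile(
    r"^c\.(?P<p1>\d+(?:[+-]\d+)?)(?:_(?P<p2>\d+(?:[+-]\d+)?))?(?P<edit>.+)$"
)
_EDITS = [
    (re.compile(r"^(?P<ref>[ACGTU])>(?P<alt>[ACGTU])$"), SUBSTITUTION),
    (re.compile(r"^delins(?P<alt>[ACGTU]+)$"), DELINS),
    (re.compile(r"^del(?:[ACGTU]+|\d+)?$"), DELETION),
    (re.compile(r"^dup(?:[ACGTU]+|\d+)?$"), DUPLICATION),
    (re.compile(r"^ins(?P<alt>[ACGTU]+)$"), INSERTION),
]


def _parse_pos(token: str) -> tuple[int, int]:
    m = _POS.fullmatch(token)
    if m is None:
        raise HgvsParseError(f"malformed position token {token!r}")
    return int(m.group("pos")), int(m.group("off") or 0)


def normalize_hgvs(text: str) -> str:
    """ASCII-fold unicode hyphens/minus signs and strip whitespace."""
    return text.strip().translate(_HYPHENS)


def parse_hgvs_c(
    text: str, transcript: Optional[TranscriptModel] = None
) -> CVariant:
    """Parse an HGVS cDNA description into a :class:`CVariant`.

    Supports the splice-region subset: substitutions, deletions, delins,
    duplications and insertions, at exonic or intronic (offset) positions,
    single positions or ranges.  When ``transcript`` is given, positions are
    validated against the transcript (cDNA bounds, offset anchoring at exon
    edges, intron lengths) and the variant is tied to its id.

    Raises :class:`HgvsParseError` for malformed syntax (the message names
    the offending token) and :class:`CoordinateError` for out-of-range
    positions.
    """
    s = normalize_hgvs(text)
    if not s.startswith("c."):
        raise HgvsParseError(f"expected 'c.' prefix in {s!r}")
    m = _HGVS.match(s)
    if m is None:
        raise HgvsParseError(f"malformed HGVS description {s!r}")
    p1, off1 = _parse_pos(m.group("p1"))
    if m.group("p2") is not None:
        p2, off2 = _parse_pos(m.group("p2"))
    else:
        p2, off2 = p1, off1

    edit_token = m.group("edit")
    for pattern, kind in _EDITS:
        em = pattern.fullmatch(edit_token)
        if em is None:
            continue
        groups = em.groupdict()
        ref = groups.get("ref")
        alt = groups.get("alt")
        if kind == SUBSTITUTION and m.group("p2") is not None:
            raise HgvsParseError(f"substitution cannot span a range: {s!r}")
        if kind == INSERTION:
            if m.group("p2") is None:
                raise HgvsParseError(f"insertion requires a two-base range: {s!r}")
        v = CVariant(
            transcript_id=transcript.transcript_id if transcript else "",
            start_pos=p1,
            start_offset=off1,
            end_pos=p2,
            end_offset=off2,
            edit=kind,
            ref=ref,
            alt=alt,
        )
        if transcript is not None:
            _validate_against(v, transcript)
        return v
    raise HgvsParseError(f"unrecognized edit token {edit_token!r} in {s!r}")


def _validate_against(v: CVariant, t: TranscriptModel) -> None:
    for pos, off in ((v.start_pos, v.start_offset), (v.end_pos, v.end_offset)):
        if not 1 <= pos <= t.cdna_length:
            raise CoordinateError(
                f"c.{pos} beyond transcript {t.transcript_id} "
                f"(length {t.cdna_length})"
            )
        # anchoring + intron length checks happen in cdna_to_genomic
        t.cdna_to_genomic(pos, off)


def format_hgvs_c(v: CVariant) -> str:
    """Deterministic normalized HGVS string; round-trips through the parser."""

    def pos_str(pos: int, off: int) -> str:
        return f"{pos}{off:+d}" if off else f"{pos}"

    left = pos_str(v.start_pos, v.start_offset)
    right = pos_str(v.end_pos, v.end_offset)
    span = left if not v.is_range else f"{left}_{right}"
    if v.edit == SUBSTITUTION:
        return f"c.{span}{v.ref}>{v.alt}"
    if v.edit == DELETION:
        return f"c.{span}del"
    if v.edit == DELINS:
        return f"c.{span}delins{v.alt}"
    if v.edit == DUPLICATION:
        return f"c.{span}dup"
    return f"c.{span}ins{v.alt}"


# ---------------------------------------------------------------------------
# extended splice region windows


@dataclass(frozen=True)
class RegionWindow:
    """One side (donor or acceptor) of the extended region at one junction.

    ``junction_id`` is the 1-based intron number (intron *n* follows exon
    *n*).  ``exonic_span`` is a 1-based inclusive cDNA interval of at most
    ``window_nt`` exonic bases adjacent to the junction; ``intronic_span``
    is an inclusive offset interval that never includes the canonical +-1,2
    positions.  ``genomic_spans`` caches the corresponding 0-based
    half-open genomic intervals for overlap tests.
    """

    junction_id: int
    side: str  # "donor" | "acceptor"
    exonic_span: tuple[int, int]
    intronic_span: Optional[tuple[int, int]]
    genomic_spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.side not in ("donor", "acceptor"):
            raise ValueError(f"side must be donor/acceptor, got {self.side!r}")
        if self.intronic_span is not None:
            o1, o2 = self.intronic_span
            if any(abs(o) < 3 for o in (o1, o2)):
                raise ValueError("intronic span may not include +-1,2 positions")


def _genomic_interval(t: TranscriptModel, a: int, b: int) -> tuple[int, int]:
    """Half-open genomic interval covering two genomic positions inclusively."""
    lo, hi = (a, b) if a <= b else (b, a)
    return lo, hi + 1


def compute_region_windows(
    transcript: TranscriptModel, window_nt: int = 50
) -> list[RegionWindow]:
    """Extended splice region windows for every internal junction.

    One donor-side window (end of exon *n* + intron *n* offsets
    +3..+``window_nt``) and one acceptor-side window (intron *n* offsets
    -``window_nt``..-3 + start of exon *n+1*) per junction.  Exonic spans
    truncate at exon boundaries; intronic spans truncate inside short
    introns.  A single-exon transcript yields an empty list.
    """
    t = transcript
    if len(t.exons) < 2:
        import warnings

        warnings.warn(
            f"transcript {t.transcript_id} has a single exon; no splice windows",
            stacklevel=2,
        )
        return []
    windows: list[RegionWindow] = []
    for i in range(len(t.exons) - 1):
        intron_no = i + 1
        intron_len = t.intron_length(i)
        donor_c = t.exon_cdna_ends[i]
        acceptor_c = donor_c + 1
        ex_start, _ = t.exon_cdna_span(i)
        _, ex_next_end = t.exon_cdna_span(i + 1)

        # donor side
        exonic = (max(ex_start, donor_c - window_nt + 1), donor_c)
        max_off = min(window_nt, intron_len)
        intronic = (3, max_off) if max_off >= 3 else None
        spans = [
            _genomic_interval(
                t, t.cdna_to_genomic(exonic[0]), t.cdna_to_genomic(exonic[1])
            )
        ]
        if intronic:
            spans.append(
                _genomic_interval(
                    t,
                    t.cdna_to_genomic(donor_c, intronic[0]),
                    t.cdna_to_genomic(donor_c, intronic[1]),
                )
            )
        windows.append(
            RegionWindow(intron_no, "donor", exonic, intronic, tuple(spans))
        )

        # acceptor side
        exonic = (acceptor_c, min(ex_next_end, acceptor_c + window_nt - 1))
        intronic = (-max_off, -3) if max_off >= 3 else None
        spans = [
            _genomic_interval(
                t, t.cdna_to_genomic(exonic[0]), t.cdna_to_genomic(exonic[1])
            )
        ]
        if intronic:
            spans.append(
                _genomic_interval(
                    t,
                    t.cdna_to_genomic(acceptor_c, intronic[0]),
                    t.cdna_to_genomic(acceptor_c, intronic[1]),
                )
            )
        windows.append(
            RegionWindow(intron_no, "acceptor", exonic, intronic, tuple(spans))
        )
    return windows


@dataclass(frozen=True)
class RegionHit:
    """Result of the extended-region membership test."""

    in_region: bool
    junction_id: Optional[int] = None
    side: Optional[str] = None
    reason: Optional[str] = None  # "canonical" | "outside" | None
    canonical_overlapping: bool = False


def _variant_genomic_interval(
    v: CVariant, t: TranscriptModel
) -> tuple[int, int]:
    g1 = t.cdna_to_genomic(v.start_pos, v.start_offset)
    g2 = t.cdna_to_genomic(v.end_pos, v.end_offset)
    return _genomic_interval(t, g1, g2)


def _canonical_positions(t: TranscriptModel) -> frozenset[int]:
    """Genomic positions of the +-1,2 dinucleotides at every junction."""
    pos = set()
    for i in range(len(t.exons) - 1):
        donor_c = t.exon_cdna_ends[i]
        for off in (1, 2):
            pos.add(t.cdna_to_genomic(donor_c, off))
        for off in (-1, -2):
            pos.add(t.cdna_to_genomic(donor_c + 1, off))
    return frozenset(pos)


def variant_in_extended_region(
    v: CVariant,
    windows: Sequence[RegionWindow],
    transcript: TranscriptModel,
) -> RegionHit:
    """Does any affected base of ``v`` fall in an extended-region window?

    A range variant (deletion/delins/dup) is in the region when *any*
    affected base overlaps a window.  Variants whose affected bases lie
    entirely at canonical +-1,2 positions return ``in_region=False`` with
    reason ``"canonical"``; a range touching both canonical and window
    bases is in the region and flagged ``canonical_overlapping``.
    """
    if v.transcript_id and v.transcript_id != transcript.transcript_id:
        raise TranscriptMismatchError(
            f"variant on {v.transcript_id} vs transcript {transcript.transcript_id}"
        )
    lo, hi = _variant_genomic_interval(v, transcript)
    canonical = _canonical_positions(transcript)
    n_affected = hi - lo
    touches_canonical = any(g in canonical for g in range(lo, hi))
    if touches_canonical and all(g in canonical for g in range(lo, hi)):
        return RegionHit(False, reason="canonical")
    for w in windows:
        for s0, s1 in w.genomic_spans:
            if lo < s1 and s0 < hi:
                return RegionHit(
                    True,
                    junction_id=w.junction_id,
                    side=w.side,
                    canonical_overlapping=touches_canonical,
                )
    return RegionHit(False, reason="outside")


# ---------------------------------------------------------------------------
# input readers


def transcript_from_dict(d: dict) -> TranscriptModel:
    """Build a model from the JSON fixture schema (exon/intron length lists)."""
    if "exons" in d:
        exons = tuple((int(a), int(b)) for a, b in d["exons"])
    else:
        exons = _exons_from_lengths(
            d["genome_start"], d["strand"], d["exon_lengths"], d["intron_lengths"]
        )
    return TranscriptModel(
        transcript_id=d["transcript_id"],
        strand=d["strand"],
        exons=exons,
        cds_start_cdna=int(d["cds_start_cdna"]),
        cds_end_cdna=int(d["cds_end_cdna"]),
        domains=tuple(
            Domain(x["name"], int(x["aa_start"]), int(x["aa_end"]), bool(x.get("critical", False)))
            for x in d.get("domains", ())
        ),
    )


def _exons_from_lengths(
    genome_start: int,
    strand: str,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
) -> tuple[tuple[int, int], ...]:
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise ValueError("need exactly one fewer intron than exons")
    exons = []
    g = genome_start
    for i, ln in enumerate(exon_lengths):
        exons.append((g, g + ln))
        if i < len(intron_lengths):
            g += ln + intron_lengths[i]
    if strand == "-":
        # transcript orientation = descending genomic start
        span_end = exons[-1][1]
        flipped = [
            (genome_start + (span_end - b), genome_start + (span_end - a))
            for a, b in exons
        ]
        return tuple(flipped)
    return tuple(exons)


def transcript_from_json(path: Union[str, Path]) -> TranscriptModel:
    with open(path) as fh:
        return transcript_from_dict(json.load(fh))


def load_myo7a_transcript() -> TranscriptModel:
    """Packaged MYO7A-like transcript model (synthetic exon architecture).

    The exon/intron coordinates are constructed, not the true RefSeq
    NM_000260.4 coordinates: junction placement in cDNA space matches the
    published variant nomenclature (49 exons, CDS 6,648 nt = 2,215 aa +
    stop, motor and FERM2 domains), which is what window and consequence
    math need; genomic offsets and intron lengths are plausible synthetic
    values.
    """
    ref = resources.files("minisplice.data") / "myo7a_nm000260_like.synthetic.json"
    return transcript_from_dict(json.loads(ref.read_text()))


def transcript_from_gff3(
    path: Union[str, Path], transcript_id: str, domains: Iterable[Domain] = ()
) -> TranscriptModel:
    """Build a model from GFF3 exon + CDS features of one mRNA (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    exons, cds = [], []
    strand = None
    for feat in db.all_features():
        parents = set(feat.attributes.get("Parent", []))
        if transcript_id not in parents and feat.id != transcript_id:
            continue
        if feat.featuretype == "exon":
            exons.append((feat.start - 1, feat.end))  # GFF3 is 1-based inclusive
            strand = feat.strand
        elif feat.featuretype == "CDS":
            cds.append((feat.start - 1, feat.end))
    if not exons:
        raise ValueError(f"no exon features for {transcript_id!r} in {path}")
    if not cds:
        raise ValueError(f"no CDS features for {transcript_id!r} in {path}")
    reverse = strand == "-"
    exons.sort(key=lambda iv: iv[0], reverse=reverse)
    cds.sort(key=lambda iv: iv[0], reverse=reverse)
    model = TranscriptModel(
        transcript_id=transcript_id,
        strand=strand or "+",
        exons=tuple(exons),
        cds_start_cdna=1,
        cds_end_cdna=sum(b - a for a, b in exons),
        domains=tuple(domains),
    )
    # locate CDS bounds in cDNA space from the genomic CDS extremes
    cds_first = cds[0][0] if not reverse else cds[0][1] - 1
    cds_last = cds[-1][1] - 1 if not reverse else cds[-1][0]
    start_c, _ = model.genomic_to_cdna(cds_first)
    end_c, _ = model.genomic_to_cdna(cds_last)
    return replace(model, cds_start_cdna=start_c, cds_end_cdna=end_c)


def read_hgvs_list(
    path: Union[str, Path], transcript: Optional[TranscriptModel] = None
) -> list[CVariant]:
    """Read one HGVS c. description per line; '#' starts a comment."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(parse_hgvs_c(line, transcript))
    return out


def variants_from_vcf(
    path: Union[str, Path], transcript: TranscriptModel
) -> list[CVariant]:
    """Map VCF records onto the transcript as :class:`CVariant`s (via cyvcf2).

    Supports SNVs and simple deletions/insertions with a shared leading
    base.  Records outside the transcript span are skipped.
    """
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        ref, alt = rec.REF, rec.ALT[0]
        try:
            if len(ref) == 1 and len(alt) == 1:
                pos, off = transcript.genomic_to_cdna(rec.POS - 1)
                if transcript.strand == "-":
                    ref, alt = _revcomp(ref), _revcomp(alt)
                out.append(
                    CVariant(transcript.transcript_id, pos, off, pos, off,
                             SUBSTITUTION, ref=ref, alt=alt)
                )
            elif len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
                g1, g2 = rec.POS, rec.POS + len(ref) - 2  # deleted bases, 0-based
                p1 = transcript.genomic_to_cdna(g1)
                p2 = transcript.genomic_to_cdna(g2)
                if transcript.strand == "-":
                    p1, p2 = p2, p1
                out.append(
                    CVariant(transcript.transcript_id, p1[0], p1[1], p2[0], p2[1],
                             DELETION)
                )
        except CoordinateError:
            continue
    return out


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]
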