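"""Quantification of minigene assay readouts.

Turns per-lane gel readouts (band size estimates + grayscale intensities,
optionally TA-clone counts for co-migrating products) into per-product
abundance fractions and a per-variant assay summary: canonical fraction,
aberrant event labels, complete-disruption flag.

The workflow mirrors how such gels are read in practice: candidate
products (canonical + enumerated event combinations) are matched to bands
by predicted length within a size tolerance reflecting agarose resolution
(default 10 nt); faint bands below an intensity floor (default 2% of lane
total) are discarded; band intensities are converted to fractions, with
clone counts splitting any band shared by co-migrating products; events
also present in the wild-type lane are "alternative" splicing, not
aberrant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .splice_events import (
    CRYPTIC_SITE_USE,
    EXON_SKIP,
    INTRON_RETENTION,
    PARTIAL_EXON_DEL,
    MinigeneConstruct,
    SpliceEvent,
    TranscriptProduct,
    reconstruct_product,
)

WT_LANE = "WT"
CONTROL_LANES = ("empty_vector", "NTC", "untransfected")


class QuantificationError(ValueError):
    pass


class NoBaselineError(QuantificationError):
    """A variant lane was interpreted without a wild-type lane."""


@dataclass(frozen=True)
class Band:
    size_nt: float
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("band intensity must be >= 0")


@dataclass(frozen=True)
class LaneReadout:
    """One gel lane: a variant, WT, or control lane."""

    lane_id: str
    bands: tuple[Band, ...]
    clone_counts: Optional[tuple[tuple[str, int], ...]] = None

    def __post_init__(self) -> None:
        if self.lane_id not in CONTROL_LANES and not self.bands:
            raise ValueError(f"lane {self.lane_id!r} has no bands")


@dataclass(frozen=True)
class BandAssignment:
    """Mapping of lane bands to candidate products."""

    matches: tuple[tuple[Band, TranscriptProduct], ...]
    unexplained: tuple[Band, ...]


@dataclass(frozen=True)
class AssaySummary:
    """Per-variant interpretation of one minigene lane."""

    variant_id: str
    canonical_fraction: float
    products: tuple[tuple[TranscriptProduct, float], ...]
    aberrant_events: tuple[str, ...] = ()
    alternative_events: tuple[str, ...] = ()

    @property
    def complete_disruption(self) -> bool:
        return self.canonical_fraction == 0.0

    @property
    def fractions_by_label(self) -> dict[str, float]:
        return {p.label: f for p, f in self.products}


def enumerate_candidates(
    construct: MinigeneConstruct,
    max_events: int = 2,
    include_pairs: bool = True,
) -> list[TranscriptProduct]:
    """Canonical + all single-event products, optionally event pairs.

    Deeper combinations are omitted by default: the candidate space grows
    combinatorially and real gels are explained by one or two events.
    """
    singles: list[SpliceEvent] = []
    for eid, _ in construct.insert_exons:
        singles.append(SpliceEvent(EXON_SKIP, eid))
    for iid, _ in construct.insert_introns:
        singles.append(SpliceEvent(INTRON_RETENTION, iid))
    products = [reconstruct_product(construct, [])]
    products += [reconstruct_product(construct, [e]) for e in singles]
    if include_pairs and max_events >= 2:
        for a, b in itertools.combinations(singles, 2):
            if a.target_id != b.target_id:
                products.append(reconstruct_product(construct, [a, b]))
    return products


def search_cryptic(
    construct: MinigeneConstruct,
    size_nt: float,
    tolerance_nt: int = 10,
    max_shift_nt: int = 100,
) -> list[TranscriptProduct]:
    """Single cryptic-site products whose length explains an orphan band.

    Exhaustively enumerates boundary shifts up to ``max_shift_nt`` at every
    junction: partial exon truncations (cryptic site inside the exon) and
    partial intron inclusions (cryptic site inside the intron).
    """
    hits = []
    candidates: list[SpliceEvent] = []
    for eid, ln in construct.insert_exons:
        for k in range(1, min(max_shift_nt, ln - 1) + 1):
            candidates.append(SpliceEvent(PARTIAL_EXON_DEL, eid, k, "p"))
            candidates.append(SpliceEvent(PARTIAL_EXON_DEL, eid, k, "q"))
    for iid, ln in construct.insert_introns:
        for k in range(1, min(max_shift_nt, ln) + 1):
            candidates.append(SpliceEvent(CRYPTIC_SITE_USE, iid, k, "p"))
            candidates.append(SpliceEvent(CRYPTIC_SITE_USE, iid, k, "q"))
    for ev in candidates:
        p = reconstruct_product(construct, [ev])
        if abs(p.length_nt - size_nt) <= tolerance_nt:
            hits.append(p)
    hits.sort(key=lambda p: abs(p.length_nt - size_nt))
    return hits


def assign_bands(
    lane: LaneReadout,
    candidates: Sequence[TranscriptProduct],
    tolerance_nt: int = 10,
    construct: Optional[MinigeneConstruct] = None,
    merge_duplicates: bool = False,
    cryptic_max_shift_nt: int = 100,
) -> BandAssignment:
    """Match each band to the nearest candidate product within tolerance.

    Ties (two candidates equally close) are broken toward the product with
    fewer events.  Bands with no candidate within tolerance are flagged
    unexplained; if ``construct`` is given, a cryptic-site search over
    single boundary shifts up to ``cryptic_max_shift_nt`` nt is attempted
    for them first.  Two bands resolving to the same product raise an
    error unless ``merge_duplicates`` is set (their intensities are then
    summed downstream).
    """
    matches: list[tuple[Band, TranscriptProduct]] = []
    unexplained: list[Band] = []
    used: dict[str, Band] = {}
    for band in lane.bands:
        best = None
        best_key = None
        for p in candidates:
            d = abs(p.length_nt - band.size_nt)
            if d > tolerance_nt:
                continue
            key = (d, len(p.events))
            if best_key is None or key < best_key:
                best, best_key = p, key
        if best is None and construct is not None:
            cryptic = search_cryptic(
                construct, band.size_nt, tolerance_nt, cryptic_max_shift_nt
            )
            if cryptic:
                best = cryptic[0]
        if best is None:
            unexplained.append(band)
            continue
        if best.label in used and not merge_duplicates:
            raise QuantificationError(
                f"two bands ({used[best.label].size_nt}, {band.size_nt} nt) "
                f"match product {best.label}; pass merge_duplicates=True to sum"
            )
        used[best.label] = band
        matches.append((band, best))
    return BandAssignment(tuple(matches), tuple(unexplained))


def quantify(
    lane: LaneReadout,
    assignment: BandAssignment,
    intensity_floor: float = 0.02,
) -> AssaySummary:
    """Densitometry fractions from an assignment.

    Bands below ``intensity_floor`` of the lane total are dropped before
    fraction computation.  A band matched to several co-migrating products
    (same label appearing in several matches after merging, or clone counts
    present) is split proportionally to TA-clone counts.
    """
    if not assignment.matches:
        raise QuantificationError(f"no assigned bands in lane {lane.lane_id}")
    total = sum(b.intensity for b, _ in assignment.matches)
    if total <= 0:
        raise QuantificationError(f"all-zero intensities in lane {lane.lane_id}")
    kept = [
        (b, p) for b, p in assignment.matches if b.intensity >= intensity_floor * total
    ]
    if not kept:
        raise QuantificationError("all bands fall below the intensity floor")
    clone = dict(lane.clone_counts or ())
    # accumulate intensity per product, splitting shared bands by clone count
    acc: dict[str, tuple[TranscriptProduct, float]] = {}
    by_band: dict[Band, list[TranscriptProduct]] = {}
    for b, p in kept:
        by_band.setdefault(b, []).append(p)
    for b, prods in by_band.items():
        if len(prods) == 1:
            shares = {prods[0].label: 1.0}
        else:
            counts = {p.label: clone.get(p.label, 0) for p in prods}
            tot = sum(counts.values())
            if tot == 0:
                shares = {p.label: 1.0 / len(prods) for p in prods}
            else:
                shares = {lbl: c / tot for lbl, c in counts.items()}
        for p in prods:
            lbl = p.label
            prev = acc.get(lbl, (p, 0.0))[1]
            acc[lbl] = (p, prev + b.intensity * shares[lbl])
    grand = sum(v for _, v in acc.values())
    products = tuple(
        (p, inten / grand) for p, inten in acc.values()
    )
    canonical = sum(f for p, f in products if p.is_canonical)
    return AssaySummary(
        variant_id=lane.lane_id,
        canonical_fraction=canonical,
        products=products,
    )


def call_aberrant(
    summary: AssaySummary,
    wt_summary: Optional[AssaySummary],
    wt_margin: float = 0.05,
) -> AssaySummary:
    """Split variant-lane events into aberrant vs alternative.

    Events absent from the WT lane (or exceeding the WT fraction of the
    same product by more than ``wt_margin``) are aberrant; events shared
    with WT at comparable abundance are naturally occurring alternative
    splicing of the construct, not variant effects.
    """
    if wt_summary is None:
        raise NoBaselineError(
            f"no wild-type baseline for variant lane {summary.variant_id}"
        )
    wt = wt_summary.fractions_by_label
    aberrant, alternative = [], []
    for p, f in summary.products:
        if p.is_canonical:
            continue
        if f > wt.get(p.label, 0.0) + wt_margin:
            aberrant.append(p.label)
        else:
            alternative.append(p.label)
    return AssaySummary(
        variant_id=summary.variant_id,
        canonical_fraction=summary.canonical_fraction,
        products=summary.products,
        aberrant_events=tuple(aberrant),
        alternative_events=tuple(alternative),
    )


def interpret_lane(
    lane: LaneReadout,
    wt_lane: LaneReadout,
    construct: MinigeneConstruct,
    tolerance_nt: int = 10,
    intensity_floor: float = 0.02,
) -> AssaySummary:
    """assign -> quantify -> call_aberrant for one variant lane."""
    candidates = enumerate_candidates(construct)
    wt = quantify(
        wt_lane,
        assign_bands(wt_lane, candidates, tolerance_nt, construct=construct),
        intensity_floor,
    )
    var = quantify(
        lane,
        assign_bands(lane, candidates, tolerance_nt, construct=construct),
        intensity_floor,
    )
    return call_aberrant(var, wt)


# ---------------------------------------------------------------------------
# TSV IO


def read_lanes_tsv(path: Union[str, Path]) -> dict[str, LaneReadout]:
    """Read lane readouts from TSV.

    Columns: ``lane_id``, ``band_size_nt``, ``intensity`` and optionally
    ``clone_product`` + ``clone_count`` (clone rows may repeat per lane).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lanes: dict[str, LaneReadout] = {}
    for lane_id, grp in df.groupby("lane_id", sort=False):
        bands = tuple(
            Band(float(r.band_size_nt), float(r.intensity))
            for r in grp.itertuples()
            if pd.notna(r.band_size_nt)
        )
        clones = None
        if "clone_product" in grp.columns:
            rows = grp.dropna(subset=["clone_product"])
            if len(rows):
                clones = tuple(
                    (str(r.clone_product), int(r.clone_count))
                    for r in rows.itertuples()
                )
        lanes[str(lane_id)] = LaneReadout(str(lane_id), bands, clones)
    return lanes
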