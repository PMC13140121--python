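"""Candidate selection funnel for extended splice region variants.

Stages, in order:

1. **QC** — depth / genotype-quality floors (defaults DP >= 10, GQ >= 20;
   these values are conventional short-read thresholds, configurable).
2. **Rarity** — keep variants with MAF <= 0.0007; salvage commoner
   variants back in when a curated database (ClinVar, DVD, HGMD) already
   calls them P or LP.  Every retained variant is tagged with its route.
3. **Region restriction** — keep variants overlapping an extended splice
   region window.  Canonical +-1,2 variants and variants already carrying
   a database P/LP assertion are routed to the second-allele pool rather
   than the candidate (functional-testing) set: established pathogenic
   alleles need no splicing assay, they anchor the trans configuration.
4. **Track assignment** — probands with a candidate plus a P/LP second
   allele follow the autosomal recessive track; probands with exactly one
   candidate under a stricter rarity bound (MAF <= 0.0002) and no second
   allele follow the autosomal dominant track.

Confirmed-cis variant pairs are collapsed into one allele-level unit
before track logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .gene_model import (
    CVariant,
    RegionHit,
    RegionWindow,
    TranscriptModel,
    parse_hgvs_c,
    variant_in_extended_region,
)

PLP = frozenset({"P", "LP"})
DB_SOURCES = frozenset({"ClinVar", "DVD", "HGMD"})

ROUTE_RARE = "rare"
ROUTE_SALVAGED = "salvaged"

BUCKET_CANDIDATE = "candidate"
BUCKET_CANONICAL = "canonical"
BUCKET_ESTABLISHED = "established"
BUCKET_OUTSIDE = "outside"

TRACK_AR = "AR"
TRACK_AD = "AD"


@dataclass(frozen=True)
class CohortVariant:
    """One observed variant with frequency, database and QC annotations."""

    variant: CVariant
    hgvs: str
    maf: float
    db_annotations: frozenset[tuple[str, str]] = frozenset()
    depth: int = 30
    genotype_quality: int = 99
    phase_group: Optional[str] = None
    assay_panel: Optional[str] = None  # "main" | "supp" | None

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"MAF {self.maf} outside [0, 1]")
        sources = [s for s, _ in self.db_annotations]
        if len(sources) != len(set(sources)):
            raise ValueError("duplicate database source annotations")

    @property
    def db_plp(self) -> bool:
        return any(cls in PLP for _, cls in self.db_annotations)


@dataclass(frozen=True)
class ProbandRecord:
    proband_id: str
    phenotype: str
    variants: tuple[CohortVariant, ...]

    def cis_groups(self) -> dict[str, tuple[CohortVariant, ...]]:
        groups: dict[str, list[CohortVariant]] = {}
        for v in self.variants:
            if v.phase_group:
                groups.setdefault(v.phase_group, []).append(v)
        return {k: tuple(vs) for k, vs in groups.items()}


# ---------------------------------------------------------------------------
# funnel stages


@dataclass(frozen=True)
class RarityResult:
    retained: tuple[CohortVariant, ...]
    salvaged: tuple[CohortVariant, ...]
    dropped: tuple[CohortVariant, ...]

    @property
    def passed(self) -> tuple[CohortVariant, ...]:
        return self.retained + self.salvaged

    def route_of(self, v: CohortVariant) -> Optional[str]:
        if v in self.retained:
            return ROUTE_RARE
        if v in self.salvaged:
            return ROUTE_SALVAGED
        return None


def qc_filter(
    vs: Sequence[CohortVariant], min_depth: int = 10, min_gq: int = 20
) -> list[CohortVariant]:
    return [
        v for v in vs if v.depth >= min_depth and v.genotype_quality >= min_gq
    ]


def rarity_filter(
    vs: Sequence[CohortVariant], maf_max: float = 0.0007
) -> RarityResult:
    """Rarity gate with database-guided salvage (routes are disjoint)."""
    retained, salvaged, dropped = [], [], []
    for v in vs:
        if v.maf <= maf_max:
            retained.append(v)
        elif v.db_plp:
            salvaged.append(v)
        else:
            dropped.append(v)
    return RarityResult(tuple(retained), tuple(salvaged), tuple(dropped))


@dataclass(frozen=True)
class RegionResult:
    candidates: tuple[CohortVariant, ...]
    canonical: tuple[CohortVariant, ...]
    established: tuple[CohortVariant, ...]
    outside: tuple[CohortVariant, ...]
    hits: dict[str, RegionHit] = field(default_factory=dict, compare=False)


def region_restrict(
    vs: Sequence[CohortVariant],
    windows: Sequence[RegionWindow],
    transcript: TranscriptModel,
) -> RegionResult:
    """Route variants into candidate / canonical / established / outside.

    Candidates are extended-region variants without a prior database P/LP
    assertion (those go to ``established`` — the second-allele pool —
    regardless of geometry, since they need no splicing assay).  Canonical
    +-1,2 variants likewise serve as second alleles, never candidates.
    """
    candidates, canonical, established, outside = [], [], [], []
    hits: dict[str, RegionHit] = {}
    for v in vs:
        hit = variant_in_extended_region(v.variant, windows, transcript)
        hits[v.hgvs] = hit
        if hit.reason == "canonical":
            canonical.append(v)
        elif v.db_plp:
            established.append(v)
        elif hit.in_region:
            candidates.append(v)
        else:
            outside.append(v)
    return RegionResult(
        tuple(candidates), tuple(canonical), tuple(established), tuple(outside),
        hits,
    )


@dataclass(frozen=True)
class AlleleUnit:
    """One allele-level candidate unit: a single variant or a cis pair."""

    variants: tuple[CohortVariant, ...]

    @property
    def unit_id(self) -> str:
        return ";".join(v.hgvs for v in self.variants)

    @property
    def maf(self) -> float:
        return max(v.maf for v in self.variants)


@dataclass(frozen=True)
class TrackAssignment:
    proband: ProbandRecord
    track: Optional[str]
    candidate_units: tuple[AlleleUnit, ...]
    second_alleles: tuple[CohortVariant, ...]
    reason: Optional[str] = None  # set when excluded


def _collapse_cis(
    proband: ProbandRecord, candidates: set[str]
) -> list[AlleleUnit]:
    """Group the proband's candidate variants into allele units."""
    groups = proband.cis_groups()
    grouped_ids = {v.hgvs for vs in groups.values() for v in vs}
    units = []
    for vs in groups.values():
        members = tuple(v for v in vs if v.hgvs in candidates)
        if members:
            units.append(AlleleUnit(members))
    for v in proband.variants:
        if v.hgvs in candidates and v.hgvs not in grouped_ids:
            units.append(AlleleUnit((v,)))
    return units


def assign_tracks(
    probands: Sequence[ProbandRecord],
    region: RegionResult,
    ad_maf_max: float = 0.0002,
) -> list[TrackAssignment]:
    """Assign each proband to the AR or AD track (or exclude with reason).

    AR: at least two variants carried, at least one extended-region
    candidate unit, and a second allele already classified P/LP.  AD:
    exactly one candidate unit, at the stricter rarity bound, with no
    second allele.  The two tracks are mutually exclusive by construction.
    """
    candidate_ids = {v.hgvs for v in region.candidates}
    second_ids = {v.hgvs for v in region.canonical + region.established}
    out = []
    for pb in probands:
        units = _collapse_cis(pb, candidate_ids)
        seconds = tuple(
            v for v in pb.variants if v.hgvs in second_ids and v.db_plp
        )
        if not units:
            out.append(
                TrackAssignment(pb, None, (), seconds, reason="no candidate variants")
            )
            continue
        if len(pb.variants) >= 2 and seconds:
            out.append(TrackAssignment(pb, TRACK_AR, tuple(units), seconds))
        elif len(units) == 1 and not seconds and units[0].maf <= ad_maf_max:
            out.append(TrackAssignment(pb, TRACK_AD, tuple(units), ()))
        else:
            out.append(
                TrackAssignment(
                    pb, None, tuple(units), seconds,
                    reason="no P/LP second allele and AD rarity bound not met",
                )
            )
    return out


# ---------------------------------------------------------------------------
# fixture loading


def _parse_db(field_: str) -> frozenset[tuple[str, str]]:
    field_ = field_.strip()
    if field_ in ("-", "", "NA"):
        return frozenset()
    out = set()
    for item in field_.split(";"):
        source, cls = item.split(":")
        if source not in DB_SOURCES:
            raise ValueError(f"unknown database source {source!r}")
        out.add((source, cls))
    return frozenset(out)


def load_proband_series(
    path: Optional[Union[str, Path]] = None,
    transcript: Optional[TranscriptModel] = None,
) -> list[ProbandRecord]:
    """Load the curated proband series TSV (packaged fixture by default)."""
    if path is None:
        ref = resources.files("minisplice.data") / "myo7a_probands.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    probands = []
    for pid, grp in df.groupby("proband_id", sort=False):
        variants = []
        phenotype = str(grp.iloc[0]["phenotype"])
        for _, r in grp.iterrows():
            hgvs = str(r["hgvs"])
            cv = parse_hgvs_c(hgvs, transcript)
            panel = str(r["panel"]).strip()
            variants.append(
                CohortVariant(
                    variant=cv,
                    hgvs=hgvs,
                    maf=float(r["maf"]),
                    db_annotations=_parse_db(str(r["db"])),
                    depth=int(r["depth"]),
                    genotype_quality=int(r["gq"]),
                    phase_group=None
                    if str(r["phase_group"]).strip() == "-"
                    else str(r["phase_group"]).strip(),
                    assay_panel=None if panel == "-" else panel,
                )
            )
        probands.append(ProbandRecord(str(pid), phenotype, tuple(variants)))
    return probands


def run_funnel(
    probands: Sequence[ProbandRecord],
    windows: Sequence[RegionWindow],
    transcript: TranscriptModel,
    maf_max: float = 0.0007,
    ad_maf_max: float = 0.0002,
) -> tuple[RarityResult, RegionResult, list[TrackAssignment]]:
    """QC -> rarity/salvage -> region restriction -> track assignment."""
    all_variants = [v for pb in probands for v in pb.variants]
    rarity = rarity_filter(qc_filter(all_variants), maf_max)
    region = region_restrict(rarity.passed, windows, transcript)
    tracks = assign_tracks(probands, region, ad_maf_max)
    return rarity, region, tracks
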