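# Methods

## Scope and model

`minisplice` operationalizes the functional-reassessment workflow for
extended splice region variants: variants within ±50 nt of an exon–intron
junction, excluding the canonical ±1,2 intronic dinucleotides. The
package covers candidate selection from a sequenced cohort, minigene
(exon-trap) assay quantification, in silico splice-score decision rules,
and RNA-aware ACMG/AMP evidence combination. It does not align reads,
call variants, run splice predictors, or analyze deep-intronic
pseudoexon-creating variants; predictor scores, lane readouts and database
annotations are inputs.

## Coordinates and HGVS

Genomic intervals are 0-based half-open; HGVS cDNA positions are 1-based;
intronic positions are (anchor, signed offset) pairs. All conversions live
in `gene_model` — one conversion site avoids the classic off-by-one trap.
Minus-strand transcripts are fully supported; windows and exon lists are
expressed in transcript orientation. The HGVS parser covers the subset
needed for splice-region work (substitution, deletion, delins,
duplication, insertion; exonic or offset positions; ranges); protein-level
syntax, inversions and complex alleles are out of scope. Parsing
normalizes the unicode hyphens common in published tables, and
`format(parse(s)) == s` holds for every curated string.

## Extended-region membership

A window pair is computed per internal junction: donor side = last 50
exonic nt + intronic offsets +3..+50; acceptor side = intronic −50..−3 +
first 50 exonic nt, truncated at short exons/introns. Membership of a
variant is decided by genomic-interval overlap: a range variant is in the
region when **any** affected base overlaps a window (this is what places a
deletion whose 5′ end sits at −51 inside the region). Variants whose
affected bases all lie at ±1,2 are "canonical" and excluded; ranges
touching both canonical and window bases count as in-region and are
flagged `canonical_overlapping`. Exonic substitutions are handled by the
same overlap rule, which is equivalent to a cDNA distance-to-junction ≤ 50
test (introns excluded from the distance).

## Selection funnel

QC floors (DP ≥ 10, GQ ≥ 20 — conventional short-read values, not
study-specified, configurable) → rarity (MAF ≤ 0.0007) with
database-guided salvage (MAF above the bound but P/LP in ClinVar, DVD or
HGMD re-enters, tagged `salvaged`) → region restriction → track
assignment. Region restriction routes variants three ways: extended-region
**candidates**; **canonical** ±1,2 alleles; and **established** alleles —
variants already carrying a database P/LP assertion. Established alleles
are second-allele anchors, never functional-testing candidates, regardless
of geometry: a known-pathogenic coding allele that happens to sit 24 nt
from a junction (e.g. a missense variant near a donor) does not need a
splicing assay. This routing is what makes the candidate set of the
curated proband series exactly the 12 variants whose interpretation was
uncertain at baseline. Confirmed-cis pairs collapse into one allele-level
unit before track logic. The AR track requires ≥2 variants, ≥1 candidate
unit and a P/LP second allele; the AD track requires exactly one candidate
unit at MAF ≤ 0.0002 and no second allele.

The curated series lists 21 distinct variant notations across 11 probands
(the accompanying prose counts 20; the discrepancy is in the source and is
preserved, not resolved, here).

## Minigene reconstruction and consequences

A construct is two trap-vector exons flanking an insert of gene exons and
introns; when the insert contains the gene's terminal exon the 3′ vector
exon is absent from the product (effective length 0), matching the assay
layout for last-exon constructs. Products are event sets — exon skip,
intron retention, partial exon loss, partial intron inclusion, cryptic
site use — with deterministic labels (ΔE6, ▼I6, ΔE7q15, ▼I3p17; a cryptic
donor shift into the intron is written as the equivalent partial intron
inclusion). Product length is canonical length plus the sum of signed
event deltas; the tests verify this arithmetic against literal
string-splicing of sequences and Biopython translation on randomized
constructs.

Frame law: frameshift ⇔ net CDS change mod 3 ≠ 0. PTC detection requires
sequences; when only lengths are available (the usual published situation)
the consequence comes from the mod-3 rule with `ptc_codon` unknown. NMD
prediction (e.g. the 50–55 nt rule) is deliberately **not** applied; PTC
positions are reported raw. Domain impact maps event targets to codon
spans; frameshifts affect every codon downstream of the first altered one.

## Densitometry

Bands are matched to candidate products (canonical + single events +
event pairs; deeper combinations off by default) by nearest predicted
length within a tolerance of 10 nt — agarose-gel resolution; the published
product lengths carry no error bars, so the tolerance is an instrument
property, configurable. Ties break toward the fewer-event product.
Unexplained bands trigger an exhaustive single-cryptic-site search over
boundary shifts ≤ 100 nt. Faint bands below 2% of lane intensity are
dropped (products can be invisible on gel). Fractions are intensity
shares; TA-clone counts split co-migrating bands proportionally.
"Complete disruption" means the canonical band is undetected (fraction
exactly 0). Events also present in the wild-type lane (within a 0.05
fraction margin) are "alternative" splicing of the construct, not variant
effects — wild-type exon-trap constructs do show natural skip isoforms.

## Evidence grading and combination

Minigene evidence is graded by a reconstruction of the published practice
(the source states no explicit Strong/Moderate boundary rule; this table
reproduces every curated assignment and is flagged as a reconstruction):

| Assay outcome | RNA code |
|---|---|
| variant lane = wild type | BP7 (RNA) Strong |
| canonical < 50% and every aberrant product truncating or a critical-domain in-frame loss | PVS1 (RNA) Strong |
| canonical < 50%, mixed/ambiguous outcomes | PVS1 (RNA) Moderate |
| mechanism discordant with disease context | PVS1 (RNA) Supporting |
| aberrant events but canonical ≥ 50% | PVS1 (RNA) Supporting |

`mechanism_concordant` is an explicit input (default true): whether a
recessive-type truncating outcome "counts" in a dominant-disease context
is a judgment call the engine must not infer. Critical domains in the
packaged model are the myosin motor (aa 1–750) and FERM2 (aa 1900–2215).

Contextual codes: PM2 below MAF 0.0007; PM1 for domain-mapped variants
with exclusively non-truncating aberrant products; PM3 for a P/LP second
allele in trans; PP4 only for a definitive USH1 phenotype. PP3 needs
SpliceAI Δ strictly > 0.2; BP4 needs Δ ≤ 0.1 with Pangolin (if present)
agreeing — the 0.1 ceiling is the conventional low-score bound, not a
study-stated value, and is configurable. PP3 is *presented but not
applied* when RNA evidence is already at Strong or above.

Combination uses the 2015 ACMG/AMP clauses encoded as data, counting
strength-modified codes at their modified strength. Simultaneous applied
pathogenic and benign evidence is a conflict → VUS (this is how
BP7_Strong + BP4 + PM2 lands on VUS rather than likely benign). A single
Strong benign criterion without pathogenic evidence reaches likely benign
(rule `LB.iii`), an extension consistent with the graded-BP7 framework.

## Synthetic data: what it emulates, and defaults

The generator emulates multi-exon genes (default 6 exons, exon lengths
60–200 nt, introns 80–300 nt) with valid CDSs (ATG, no internal stop,
terminal stop — translation-checked), minigene lanes, and predictor
scores. Defaults encode the study conditions this package models:

* splice-disrupting variants abolish the canonical product with
  probability 2/3 (six of the nine assayed variants did), otherwise leave
  a residual canonical fraction of 0.25 (the <50% regime);
* band intensities carry multiplicative lognormal noise, cv = 0.1 —
  densitometry error is scale-proportional;
* simulated cryptic shifts span 15–80 nt: a shift below gel resolution
  (~10 nt) would co-migrate with the canonical band and is not a
  detectable banding phenotype;
* SpliceAI-like scores are Beta-distributed, mean 0.8 (concentration 12)
  for true effects and 0.035 (concentration 25) for neutral variants;
  overlapping parameterizations exercise the 0.2 threshold.

Ground-truth labels follow the package's own rules (disruptive + rare +
P/LP second allele → LP), so end-to-end recovery is a closed-loop
consistency check of the pipeline — it shows internal coherence, not
external validity. What the simulator does **not** emulate: band-size
estimation error, heteroduplex artifacts, PCR amplification bias between
short and long products, partially penetrant effects, tissue-specific
splicing, or real predictor error structure. Passing tests therefore
say nothing about how often real gels are misread.

## Problem sizes and numerics

The oracle-equivalence check runs 1,000 random constructs; fraction
recovery uses 200 lanes; closed-loop recovery uses 100 variants — sizes at
which the Monte-Carlo bounds asserted in the tests are comfortably stable
while the whole suite runs in seconds. Fractions sum to 1 within 1e-9;
band-size tolerance 10 nt; intensity floor 2%; WT-sharing margin 0.05.
All randomness flows from `numpy.random.default_rng` seeded per
configuration; identical seeds give byte-identical outputs.

## Transcript fixture

The packaged transcript is a constructed ("synthetic" in filename and
docstring) 49-exon model emulating the *MYO7A* reference NM_000260.4:
cDNA junction placement matches the published variant nomenclature (exon
ends at c.592, 1200, 1523, 1797, 3375, 3630, 5043, 5856, 6051, 6558;
starts at 593, 1201, 1798, 6052), CDS 6,648 nt (2,215 aa + stop, the true
myosin VIIa length), with motor/FERM2 domain bounds placed so the nine
assayed variants split 6:3 between them. Genomic anchor and intron
lengths are plausible synthetic values — window math and consequence
calls depend only on the cDNA-space junction structure, which is exact.

## Known limitations

* The PVS1 (RNA) Strong/Moderate boundary is a reconstruction (above).
* PTC location requires sequences; length-only inputs fall back to mod-3.
* Candidate enumeration searches single events and pairs only.
* The engine implements the categorical 2015 combining rules, not the
  Bayesian point system; population codes beyond PM2 (BA1/BS1/BS2) are out
  of scope.
* VCF input covers SNVs and simple indels with a shared leading base.
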