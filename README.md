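# minisplice

Interpretation of **extended splice region variants** — variants within
±50 nt of an exon–intron junction but outside the canonical ±1,2
dinucleotides. Such variants are routinely left as variants of uncertain
significance (VUS) in hearing-loss genes like *MYO7A* (Usher syndrome type
1B, DFNB2, DFNA11), because splice impact outside the invariant GT/AG
sites is context-dependent and poorly captured by prediction alone.

`minisplice` is a tested, reusable pipeline for the workflow that resolves
them:

1. **Candidate selection** (`cohort_filter`): rarity filter
   (MAF ≤ 7×10⁻⁴) with database-guided salvage of known P/LP alleles,
   restriction to extended splice region windows, and assignment of
   probands to autosomal-recessive (candidate + P/LP second allele in
   trans) or autosomal-dominant (single candidate, MAF ≤ 2×10⁻⁴) tracks.
2. **Coordinate backbone** (`gene_model`): transcript models (GFF3 or
   JSON), a restricted HGVS cDNA parser with intronic offsets
   (`c.6052-51_6052-11del`), cDNA↔genomic mapping on both strands, and
   ±50-nt window computation excluding the ±1,2 positions.
3. **Minigene assay analysis** (`splice_events`, `minigene_quant`):
   exon-trap construct models, splice-event nomenclature (ΔE6, ▼I6,
   ΔE7q15…), product-length reconstruction, frameshift / in-frame / PTC
   consequences, gel band→product assignment with cryptic-site search, and
   densitometry fractions with TA-clone splitting of co-migrating bands.
4. **In silico rules** (`insilico`): SpliceAI Δ > 0.2 (strict), the ENIGMA
   MaxEntScan mutant-score floor (Alt < 6.2), and PP3/BP4 assignment from
   supplied scores (predictors are never executed here).
5. **RNA-aware ACMG/AMP engine** (`acmg_engine`): graded PVS1 (RNA) /
   BP7 (RNA) from assay outcomes, contextual PM1/PM2/PM3/PP4, PP3 gating
   under Strong RNA evidence, and the 2015 combining rules encoded as
   data, with conflict → VUS.
6. **Ground-truth simulation** (`synthetic_data`): gene models with valid
   CDSs, minigene lanes with multiplicative lognormal band noise, and
   effect-correlated predictor scores, so the whole pipeline is testable
   offline against known truth.

Packaged fixtures include a synthetic 49-exon transcript model emulating
the *MYO7A* reference NM_000260.4 architecture, a curated 11-proband
series with 21 variant notations, the corresponding ACMG/AMP evidence
table, and predictor scores.

## Worked example

```python
from minisplice import (
    load_myo7a_transcript, compute_region_windows, parse_hgvs_c,
    variant_in_extended_region, classify_evidence_table,
)
from minisplice.cohort_filter import load_proband_series, run_funnel

t = load_myo7a_transcript()
windows = compute_region_windows(t)           # 96 windows (48 junctions x 2)

v = parse_hgvs_c("c.6052-51_6052-11del", t)   # intronic 41-nt deletion
hit = variant_in_extended_region(v, windows, t)
print(hit.in_region, hit.junction_id, hit.side)
# True 44 acceptor  -- the deletion's 3' end reaches the -50..-3 window

probands = load_proband_series(transcript=t)
_, region, tracks = run_funnel(probands, windows, t)
print(len(region.candidates),
      sum(x.track == "AR" for x in tracks),
      sum(x.track == "AD" for x in tracks))
# 12 8 3  -- 12 extended-region candidates; 8 AR and 3 AD probands

tiers = [c.tier for c in classify_evidence_table().values()]
print(tiers.count("LP"), tiers.count("VUS"))
# 8 3  -- evidence combination upgrades 8 units to LP, 3 remain VUS
```

The funnel keeps exactly the 12 extended-region candidates (a confirmed
cis pair is analyzed as one allele-level unit, hence 11 evidence rows),
and the ACMG/AMP engine reclassifies 8 of the 11 units to likely
pathogenic while 3 stay VUS — two via BP7_Strong (RNA) conflicting with
PM2, one via RNA evidence capped at Supporting strength.

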