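{
  "transcript_id": "NM_000260.4",
  "synthetic": true,
  "note": "Synthetic 49-exon transcript model emulating the MYO7A reference transcript NM_000260.4. cDNA junction placement matches the published variant nomenclature (exon ends at c.592, 1200, 1523, 1797, 3375, 3630, 5043, 5856, 6051, 6558; CDS 6648 nt = 2215 aa + stop); genomic anchor and intron lengths are constructed plausible values, not RefSeq coordinates.",
  "strand": "+",
  "genome_start": 77128000,
  "exon_lengths": [120, 100, 100, 100, 90, 82, 108, 110, 130, 130, 130, 120, 60, 70, 73, 274, 333, 120, 130, 130, 130, 130, 130, 150, 150, 175, 125, 130, 170, 120, 120, 130, 130, 130, 130, 140, 140, 203, 147, 150, 130, 180, 206, 195, 189, 120, 110, 88, 90],
  "intron_lengths": [1500, 900, 2100, 800, 1200, 101, 700, 1800, 950, 1100, 1200, 850, 600, 2000, 760, 1400, 980, 720, 1600, 880, 1300, 740, 2200, 910, 1050, 830, 1250, 690, 1700, 860, 940, 1150, 780, 2400, 820, 990, 1350, 870, 1450, 930, 1020, 800, 1100, 300, 760, 890, 640, 970],
  "cds_start_cdna": 1,
  "cds_end_cdna": 6648,
  "domains": [
    {"name": "myosin motor", "aa_start": 1, "aa_end": 750, "critical": true},
    {"name": "IQ", "aa_start": 751, "aa_end": 940, "critical": false},
    {"name": "MyTH4-1", "aa_start": 1017, "aa_end": 1253, "critical": false},
    {"name": "SH3", "aa_start": 1603, "aa_end": 1672, "critical": false},
    {"name": "FERM2", "aa_start": 1900, "aa_end": 2215, "critical": true}
  ]
}
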