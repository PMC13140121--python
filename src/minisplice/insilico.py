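"""Decision rules over externally computed splice predictor scores.

Scores (SpliceAI delta, Pangolin, MaxEntScan Ref/Alt, dbscSNV) are inputs
read from TSV — the predictors themselves are never run here.  The rules:

* SpliceAI supports impact when the delta score is strictly greater than
  0.2 (the conventional interpretive threshold);
* the MaxEntScan rule follows the ENIGMA convention: a mutant (Alt) site
  score below 6.2 is likely to affect splicing; the diff score
  (Ref - Alt) is carried for reporting; sites that cannot be scored (e.g.
  small intronic deletions) are not applicable;
* the computational ACMG code is PP3 when SpliceAI supports impact and BP4
  when both SpliceAI and Pangolin (if present) are at or below a low-score
  ceiling (default 0.1).

dbscSNV scores are ingested and reported but drive no code by default.
Missing scores are represented explicitly (None / NA), never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

SUPPORTS_IMPACT = "supports_impact"
NO_SUPPORT = "no_support"
MISSING = "missing"

LIKELY_AFFECTS = "likely_affects"
NO_EFFECT = "no_effect"
NOT_APPLICABLE = "not_applicable"

PP3 = "PP3"
BP4 = "BP4"
NO_CODE = "none"


@dataclass(frozen=True)
class PredictionScores:
    """Predictor scores for one variant; None encodes a missing score."""

    variant_id: str
    spliceai_delta: Optional[float] = None
    spliceai_window_nt: int = 50
    pangolin: Optional[float] = None
    mes_ref: Optional[float] = None
    mes_alt: Optional[float] = None
    dbscsnv_ada: Optional[float] = None
    dbscsnv_rf: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("spliceai_delta", "pangolin", "dbscsnv_ada", "dbscsnv_rf"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def mes_diff(self) -> Optional[float]:
        """Ref score minus Alt score; None when either side is missing."""
        if self.mes_ref is None or self.mes_alt is None:
            return None
        return self.mes_ref - self.mes_alt


def spliceai_verdict(s: PredictionScores, threshold: float = 0.2) -> str:
    """Strictly-greater-than threshold rule on the SpliceAI delta score."""
    if s.spliceai_delta is None:
        return MISSING
    return SUPPORTS_IMPACT if s.spliceai_delta > threshold else NO_SUPPORT


def mes_verdict(s: PredictionScores, alt_floor: float = 6.2) -> str:
    """MaxEntScan mutant-site rule: Alt score below ``alt_floor`` flags impact."""
    if s.mes_alt is None:
        return NOT_APPLICABLE
    return LIKELY_AFFECTS if s.mes_alt < alt_floor else NO_EFFECT


def computational_code(s: PredictionScores, bp4_ceiling: float = 0.1) -> str:
    """PP3 / BP4 / none from the score set.

    PP3 and BP4 are mutually exclusive by construction: PP3 needs the
    SpliceAI delta above 0.2, BP4 needs it at or below ``bp4_ceiling``
    (and Pangolin, when present, likewise).
    """
    if s.spliceai_delta is None and s.pangolin is None:
        warnings.warn(
            f"no computational scores for {s.variant_id}; no code assigned",
            stacklevel=2,
        )
        return NO_CODE
    if spliceai_verdict(s) == SUPPORTS_IMPACT:
        return PP3
    if (
        s.spliceai_delta is not None
        and s.spliceai_delta <= bp4_ceiling
        and (s.pangolin is None or s.pangolin <= bp4_ceiling)
    ):
        return BP4
    return NO_CODE


def read_scores_tsv(path: Union[str, Path]) -> dict[str, PredictionScores]:
    """Read predictor scores from TSV (missing values as NA, never 0)."""
    df = pd.read_csv(path, sep="\t", comment="#")

    def opt(row, col) -> Optional[float]:
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    out = {}
    for _, row in df.iterrows():
        s = PredictionScores(
            variant_id=str(row["variant_id"]),
            spliceai_delta=opt(row, "spliceai_delta"),
            spliceai_window_nt=int(row.get("spliceai_window_nt", 50) or 50),
            pangolin=opt(row, "pangolin"),
            mes_ref=opt(row, "mes_ref"),
            mes_alt=opt(row, "mes_alt"),
            dbscsnv_ada=opt(row, "dbscsnv_ada"),
            dbscsnv_rf=opt(row, "dbscsnv_rf"),
        )
        out[s.variant_id] = s
    return out


def load_myo7a_scores() -> dict[str, PredictionScores]:
    """Packaged predictor scores for the curated variant set (synthetic
    stand-ins consistent with the published qualitative statements)."""
    from importlib import resources

    ref = resources.files("minisplice.data") / "predictor_scores.synthetic.tsv"
    with resources.as_file(ref) as p:
        return read_scores_tsv(p)
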