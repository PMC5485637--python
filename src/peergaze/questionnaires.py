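"""Questionnaire scoring: SAS-A (social anxiety) and PDS (pubertal status).

SAS-A: 22 items on a 1-5 scale; 18 statements are scored, 4 fillers are
ignored.  The total therefore spans 18-90; the band 50-54 marks the commonly
used clinical cut-off region.  This package fixes the filler items at
1-based positions 2, 8, 15 and 22 as its schema convention (the instrument's
scoring depends only on which 18 items are summed).

PDS: four development items on a 1 ("not yet begun") to 4 ("seems completed")
scale plus the menarche question (yes = 4, no = 1) as item five; the category
score is the five-item sum divided by 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["SAS_A_N_ITEMS", "SAS_A_FILLER_ITEMS", "SAS_A_CUTOFF_BAND",
           "SASAScore", "score_sas_a", "score_pds"]

SAS_A_N_ITEMS = 22
#: 1-based positions of the four filler items.
SAS_A_FILLER_ITEMS = (2, 8, 15, 22)
SAS_A_CUTOFF_BAND = (50, 54)
_SCORED_IDX = tuple(i for i in range(SAS_A_N_ITEMS)
                    if (i + 1) not in SAS_A_FILLER_ITEMS)


@dataclass(frozen=True)
class SASAScore:
    total: int
    cutoff_band: tuple[int, int] = SAS_A_CUTOFF_BAND

    @property
    def band_position(self) -> str:
        """'below', 'within' or 'above' the clinical cut-off band."""
        lo, hi = self.cutoff_band
        if self.total < lo:
            return "below"
        if self.total > hi:
            return "above"
        return "within"


def score_sas_a(item_responses: Sequence[int]) -> SASAScore:
    """Sum the 18 scored SAS-A statements (fillers ignored)."""
    if len(item_responses) != SAS_A_N_ITEMS:
        raise ValueError(f"SAS-A has {SAS_A_N_ITEMS} items, "
                         f"got {len(item_responses)}")
    for i, r in enumerate(item_responses, start=1):
        if not (isinstance(r, (int,)) or float(r).is_integer()) or not 1 <= int(r) <= 5:
            raise ValueError(f"SAS-A item {i} response {r!r} outside 1-5")
    total = int(sum(int(item_responses[i]) for i in _SCORED_IDX))
    return SASAScore(total)


def score_pds(items: Sequence[int], menarche: bool) -> float:
    """PDS category score: (four development items + menarche as 4/1) / 5."""
    if len(items) != 4:
        raise ValueError("PDS takes four development items plus menarche")
    for i, r in enumerate(items, start=1):
        if int(r) != r or not 1 <= int(r) <= 4:
            raise ValueError(f"PDS item {i} response {r!r} outside 1-4")
    menarche_score = 4 if menarche else 1
    return (sum(int(r) for r in items) + menarche_score) / 5.0
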