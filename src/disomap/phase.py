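"""Liquid-liquid phase separation calls from droplet-promoting probabilities.

A protein with overall phase-separation probability pLLPS >= 0.60 is a
droplet driver.  One with a lower pLLPS but at least one droplet-promoting
region (DPR: a run of consecutive residues with droplet-promoting
probability >= 0.60) is a droplet client; otherwise no call is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import PerResidueTrack, RegionSet
from .disorder import extract_regions

PLLPS_THRESHOLD = 0.60
DPR_MIN_LENGTH = 5

DRIVER = "driver"
CLIENT = "client"
NONE = "none"


@dataclass
class LLPSCall:
    pllps: float
    dprs: RegionSet
    classification: str


def extract_dprs(p_dp: PerResidueTrack, threshold: float = PLLPS_THRESHOLD,
                 min_length: int = DPR_MIN_LENGTH) -> RegionSet:
    """Droplet-promoting regions: threshold runs of the p_DP track."""
    p_dp.check_range(0, 1)
    return extract_regions(p_dp, threshold, min_length=min_length, kind="DPR")


def classify_llps(pllps: float, dprs: RegionSet) -> LLPSCall:
    """Driver / client / none call from pLLPS and the extracted DPRs."""
    if not 0.0 <= pllps <= 1.0:
        raise ValueError(f"pLLPS {pllps} outside [0, 1]")
    if pllps >= PLLPS_THRESHOLD:
        label = DRIVER
    elif len(dprs) > 0:
        label = CLIENT
    else:
        label = NONE
    return LLPSCall(pllps, dprs, label)


def annotate_overlaps(a: RegionSet, b: RegionSet) -> pd.DataFrame:
    """Pairwise overlaps between two region sets on the same protein.

    One row per intersecting (a, b) pair with the intersection length and
    the Jaccard index of the two intervals (adjacent intervals do not
    overlap under inclusive coordinates).
    """
    if a.protein_id != b.protein_id:
        raise ValueError(
            f"protein id mismatch: {a.protein_id!r} vs {b.protein_id!r}")
    rows = []
    for ra in a:
        for rb in b:
            lo = max(ra.start, rb.start)
            hi = min(ra.end, rb.end)
            if lo > hi:
                continue
            inter = hi - lo + 1
            union = ra.length + rb.length - inter
            rows.append({
                "a_start": ra.start, "a_end": ra.end, "a_kind": ra.kind,
                "b_start": rb.start, "b_end": rb.end, "b_kind": rb.kind,
                "intersection": inter,
                "jaccard": inter / union,
            })
    return pd.DataFrame(rows, columns=["a_start", "a_end", "a_kind",
                                       "b_start", "b_end", "b_kind",
                                       "intersection", "jaccard"])
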