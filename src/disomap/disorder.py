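"""Consensus disorder profiling.

A residue is called disordered when its predictor score is >= 0.5.  The
mean disorder profile (MDP) averages several per-residue predictors; the
percentage of predicted disordered residues (PPDR) summarises a track,
and proteins are binned as highly ordered (PPDR < 10%), moderately
disordered (10% <= PPDR < 30%) or highly disordered (PPDR >= 30%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import PerResidueTrack, Region, RegionSet

DISORDER_THRESHOLD = 0.5

HIGHLY_ORDERED = "highly_ordered"
MODERATELY_DISORDERED = "moderately_disordered"
HIGHLY_DISORDERED = "highly_disordered"


@dataclass
class DisorderSummary:
    ppdr_by_predictor: dict[str, float]
    ppdr_mdp: float
    category_by_predictor: dict[str, str]
    category_mdp: str


def compute_mdp(tracks: list[PerResidueTrack]
                ) -> tuple[PerResidueTrack, PerResidueTrack]:
    """Mean disorder profile and its per-residue spread.

    Returns the per-residue arithmetic mean over non-missing predictor
    scores (track ``MDP``) and the per-residue sample standard deviation
    (``MDP_sd``, the error band; 0 where only one predictor reports).
    A residue missing in every track is an error.
    """
    if not tracks:
        raise ValueError("need at least one track")
    length = len(tracks[0])
    if any(len(t) != length for t in tracks):
        raise ValueError("tracks have unequal lengths")
    for t in tracks:
        t.check_range(0, 1)
    stacked = np.vstack([t.values for t in tracks])
    counts = (~np.isnan(stacked)).sum(axis=0)
    if (counts == 0).any():
        pos = int(np.flatnonzero(counts == 0)[0]) + 1
        raise ValueError(f"residue {pos} is missing in all tracks")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
        sd = np.nanstd(stacked, axis=0, ddof=1)
    sd[counts == 1] = 0.0
    pid = tracks[0].protein_id
    return (PerResidueTrack(pid, "MDP", mean),
            PerResidueTrack(pid, "MDP_sd", sd))


def ppdr(track: PerResidueTrack, threshold: float = DISORDER_THRESHOLD) -> float:
    """Percentage of (non-missing) residues at or above the threshold."""
    present = track.mask
    n = int(present.sum())
    if n == 0:
        raise ValueError("track has no scores")
    return 100.0 * float((track.values[present] >= threshold).sum()) / n


def classify_disorder(ppdr_value: float) -> str:
    """Bin a PPDR percentage into the three standard disorder categories."""
    if not 0.0 <= ppdr_value <= 100.0:
        raise ValueError(f"PPDR {ppdr_value} outside [0, 100]")
    if ppdr_value < 10.0:
        return HIGHLY_ORDERED
    if ppdr_value < 30.0:
        return MODERATELY_DISORDERED
    return HIGHLY_DISORDERED


def extract_regions(track: PerResidueTrack, threshold: float,
                    min_length: int = 1, kind: str = "IDPR") -> RegionSet:
    """Maximal runs of consecutive residues with value >= threshold.

    Missing values break runs; runs shorter than ``min_length`` are
    dropped.  Regions are 1-based inclusive.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    above = np.zeros(len(track), dtype=bool)
    above[track.mask] = track.values[track.mask] >= threshold
    padded = np.concatenate(([False], above, [False])).astype(int)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1) + 1   # to 1-based
    ends = np.flatnonzero(diff == -1)        # inclusive, 1-based
    regions = [Region(int(s), int(e), kind)
               for s, e in zip(starts, ends) if e - s + 1 >= min_length]
    return RegionSet(track.protein_id, regions)


def summarize_disorder(tracks: list[PerResidueTrack],
                       threshold: float = DISORDER_THRESHOLD) -> DisorderSummary:
    mdp, _ = compute_mdp(tracks)
    by_pred = {t.name: ppdr(t, threshold) for t in tracks}
    return DisorderSummary(
        ppdr_by_predictor=by_pred,
        ppdr_mdp=ppdr(mdp, threshold),
        category_by_predictor={k: classify_disorder(v) for k, v in by_pred.items()},
        category_mdp=classify_disorder(ppdr(mdp, threshold)),
    )
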