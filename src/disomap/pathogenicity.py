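"""Aggregation of per-variant missense pathogenicity scores.

Scores follow the AlphaMissense convention: 0-1 with fixed class cutoffs
(< 0.34 likely benign, 0.34-0.564 ambiguous, > 0.564 likely pathogenic;
both boundary values fall in the ambiguous band so the three classes
partition [0, 1]).
"""

from __future__ import annotations

import numpy as np

from .datatypes import PerResidueTrack, ProteinSequence, VariantScoreTable
from .io_formats import parse_variant

BENIGN_CUTOFF = 0.34
PATHOGENIC_CUTOFF = 0.564

LIKELY_BENIGN = "likely_benign"
AMBIGUOUS = "ambiguous"
LIKELY_PATHOGENIC = "likely_pathogenic"


def classify_score(score: float) -> str:
    """Three-class call for a single pathogenicity score."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score < BENIGN_CUTOFF:
        return LIKELY_BENIGN
    if score <= PATHOGENIC_CUTOFF:
        return AMBIGUOUS
    return LIKELY_PATHOGENIC


def per_residue_mean(table: VariantScoreTable, length: int) -> PerResidueTrack:
    """Mean score per residue over all substitutions observed there.

    Residues with no entries get a missing value (never 0): typical
    variant tables omit synonymous rows and may omit whole positions.
    """
    df = table.entries
    if len(df) and df["pos"].max() > length:
        raise ValueError("variant position beyond given length")
    sums = np.zeros(length)
    counts = np.zeros(length)
    idx = df["pos"].to_numpy(dtype=int) - 1
    np.add.at(sums, idx, df["score"].to_numpy(dtype=float))
    np.add.at(counts, idx, 1.0)
    values = np.full(length, np.nan)
    hit = counts > 0
    values[hit] = sums[hit] / counts[hit]
    return PerResidueTrack(table.protein_id, "mean_pathogenicity", values)


def protein_mean(table: VariantScoreTable) -> float:
    """Arithmetic mean over all variant entries (the headline number)."""
    if len(table) == 0:
        raise ValueError("empty variant table")
    return float(table.entries["score"].mean())


def protein_mean_report(table: VariantScoreTable, length: int,
                        rel_tol: float = 1e-9) -> dict:
    """Per-variant mean and mean of per-residue means, with a consistency flag.

    The two agree when every residue carries the same number of entries;
    they are both reported because either convention is defensible.
    """
    per_variant = protein_mean(table)
    track = per_residue_mean(table, length)
    per_residue = float(np.nanmean(track.values))
    agree = abs(per_variant - per_residue) <= rel_tol * max(abs(per_variant), 1e-300)
    return {"mean_per_variant": per_variant,
            "mean_of_residue_means": per_residue,
            "consistent": bool(agree)}


def lookup_variant(table: VariantScoreTable, variant: str,
                   sequence: ProteinSequence | None = None
                   ) -> tuple[float, str]:
    """Score and class of one variant, in either ``G61E`` or ``p.Gly61Glu``
    notation; the reference residue is cross-checked when possible."""
    ref, pos, alt = parse_variant(variant)
    if sequence is not None:
        actual = sequence.residue_at(pos)
        if actual != ref:
            raise ValueError(
                f"reference mismatch: variant says {ref}{pos}, sequence has "
                f"{actual} at position {pos}")
    df = table.entries
    hit = df[(df["pos"] == pos) & (df["alt"] == alt)]
    if len(hit) == 0:
        raise KeyError(f"variant {variant!r} not in table")
    row = hit.iloc[0]
    if row["ref"] != ref:
        raise ValueError(
            f"reference mismatch: variant says {ref}{pos}, table has {row['ref']}")
    score = float(row["score"])
    return score, classify_score(score)
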