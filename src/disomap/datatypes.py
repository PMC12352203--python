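"""Core containers shared by every stage of the pipeline.

All residue coordinates are 1-based and intervals are inclusive on both
ends, matching the convention used throughout the structural-disorder
literature ("residues 1-14" includes residue 14).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

#: The 20 standard one-letter amino-acid codes, alphabetical.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SequenceAlphabetError(ValueError):
    """A residue code outside the standard 20-letter alphabet."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified protein chain of one-letter residue codes.

    Positions are 1-based: ``seq[1]`` via :meth:`residue_at` is the first
    residue, matching variant notation such as ``G61E``.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must contain at least one residue")
        if not self.residues.isupper() or not self.residues.isalpha():
            bad = next(i for i, r in enumerate(self.residues, start=1)
                       if not (r.isalpha() and r.isupper()))
            raise SequenceAlphabetError(
                f"illegal residue code {self.residues[bad - 1]!r} at position {bad}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """One-letter code at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.residues[position - 1]

    def nonstandard_positions(self) -> list[int]:
        """1-based positions whose code is not one of the standard 20."""
        return [i for i, r in enumerate(self.residues, start=1)
                if r not in STANDARD_AMINO_ACIDS]

    def require_standard(self) -> None:
        bad = self.nonstandard_positions()
        if bad:
            pos = bad[0]
            raise SequenceAlphabetError(
                f"non-standard residue {self.residues[pos - 1]!r} at position {pos}")


@dataclass
class PerResidueTrack:
    """A named numeric value per residue, aligned to a sequence.

    Missing values are represented as ``nan``.  Tracks that carry
    probabilities or normalised scores live in [0, 1]; pLDDT lives in
    [0, 100].  Range checks are the responsibility of the readers and
    generators that know what the track means.
    """

    protein_id: str
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("track values must be a non-empty 1-D array")
        if np.isinf(self.values).any():
            raise ValueError("track values must be finite or missing (nan)")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a value is present."""
        return ~np.isnan(self.values)

    def check_range(self, lo: float = 0.0, hi: float = 1.0) -> "PerResidueTrack":
        v = self.values[self.mask]
        if v.size and (v.min() < lo or v.max() > hi):
            raise ValueError(
                f"track {self.name!r} has values outside [{lo}, {hi}]")
        return self


class Region(NamedTuple):
    """A 1-based inclusive interval with a kind label (e.g. IDPR, DPR)."""

    start: int
    end: int
    kind: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    """Typed intervals on a sequence; per kind they are sorted and disjoint."""

    protein_id: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = [Region(*r) for r in self.regions]
        for r in self.regions:
            if not 1 <= r.start <= r.end:
                raise ValueError(f"invalid region {r}")
        self.regions.sort(key=lambda r: (r.kind, r.start))
        by_kind: dict[str, Region] = {}
        for r in self.regions:
            prev = by_kind.get(r.kind)
            if prev is not None and r.start <= prev.end:
                raise ValueError(
                    f"overlapping {r.kind} regions {prev} and {r}")
            by_kind[r.kind] = r

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def of_kind(self, kind: str) -> list[Region]:
        return [r for r in self.regions if r.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.regions, columns=["start", "end", "kind"])

    def to_bed_frame(self, chrom: str | None = None) -> pd.DataFrame:
        """BED-like export: 0-based half-open coordinates."""
        return pd.DataFrame({
            "chrom": chrom or self.protein_id,
            "start": [r.start - 1 for r in self.regions],
            "end": [r.end for r in self.regions],
            "name": [r.kind for r in self.regions],
        })


@dataclass
class VariantScoreTable:
    """Missense pathogenicity scores per (position, alternate residue).

    Backed by a DataFrame with columns ``pos`` (1-based int), ``ref``,
    ``alt`` (one-letter codes), ``score`` (in [0, 1]) and ``class_label``.
    """

    protein_id: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        required = {"pos", "ref", "alt", "score"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"variant table missing columns {sorted(missing)}")
        if "class_label" not in df.columns:
            df = df.assign(class_label=None)
        df = df.astype({"pos": int, "ref": str, "alt": str, "score": float})
        if len(df):
            if (df["score"].lt(0) | df["score"].gt(1)).any():
                raise ValueError("pathogenicity scores must lie in [0, 1]")
            if (df["ref"] == df["alt"]).any():
                row = df[df["ref"] == df["alt"]].iloc[0]
                raise ValueError(
                    f"variant with ref == alt at position {row['pos']}")
            if df.duplicated(subset=["pos", "alt"]).any():
                dup = df[df.duplicated(subset=["pos", "alt"])].iloc[0]
                raise ValueError(
                    f"duplicate entry for position {dup['pos']} alt {dup['alt']}")
        self.entries = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_records(cls, protein_id: str,
                     records: Iterable[tuple]) -> "VariantScoreTable":
        """Build from (pos, ref, alt, score[, class_label]) tuples."""
        rows = list(records)
        cols = ["pos", "ref", "alt", "score", "class_label"]
        if rows and len(rows[0]) == 4:
            cols = cols[:4]
        return cls(protein_id, pd.DataFrame(rows, columns=cols))

    def attach_sequence(self, seq: ProteinSequence) -> None:
        """Validate positions and reference residues against a sequence."""
        if len(self.entries) == 0:
            return
        if self.entries["pos"].max() > seq.length:
            raise ValueError("variant position beyond sequence length")
        refs = np.array([seq.residue_at(p) for p in self.entries["pos"]])
        mismatch = refs != self.entries["ref"].to_numpy()
        if mismatch.any():
            i = int(np.flatnonzero(mismatch)[0])
            row = self.entries.iloc[i]
            raise ValueError(
                f"reference mismatch at position {row['pos']}: table says "
                f"{row['ref']}, sequence has {refs[i]}")
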