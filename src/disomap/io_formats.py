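"""Readers and writers for the external formats the pipeline touches.

Supported formats
-----------------
* FASTA protein sequences (Biopython).
* AlphaMissense-style variant TSV: columns ``uniprot_id``,
  ``protein_variant``, ``am_pathogenicity``, ``am_class``; ``#`` comments.
* Per-residue disorder CSV: ``res_index``, ``res``, then one numeric
  column per predictor (the RIDAO-style aggregated export).
* FuzDrop-style droplet-promoting-probability CSV with a
  ``# pLLPS=<x>`` header line.
* STRING-style weighted edge list TSV (``node1``, ``node2``,
  ``combined_score`` on the 0-1000 integer scale).
* PDB / mmCIF structures (gemmi), for pLDDT extraction and for
  repainting B-factors with an arbitrary per-residue track.
"""

from __future__ import annotations

import logging
import math
import re
from io import StringIO
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import (PerResidueTrack, ProteinSequence, SequenceAlphabetError,
                        VariantScoreTable)

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "none", "null", "."}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: str = "strict") -> ProteinSequence:
    """Read the first record of a FASTA file.

    The sequence id is the UniProt accession when the header follows the
    ``sp|ACC|NAME`` convention, otherwise the first header token.

    Parameters
    ----------
    alphabet
        ``"strict"`` rejects residues outside the standard 20-letter
        alphabet; ``"flag"`` keeps them and logs a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec = records[0]
    ident = rec.id
    m = re.match(r"^(?:sp|tr)\|([^|]+)\|", ident)
    if m:
        ident = m.group(1)
    seq = ProteinSequence(ident, str(rec.seq).strip().upper())
    if alphabet == "strict":
        seq.require_standard()
    else:
        bad = seq.nonstandard_positions()
        if bad:
            logger.warning("%s: %d non-standard residues (first at %d)",
                           ident, len(bad), bad[0])
    return seq


def write_fasta(seq: ProteinSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.id}\n")
        for i in range(0, seq.length, width):
            fh.write(seq.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# AlphaMissense variant tables

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}

_VARIANT_RE = re.compile(
    r"^(?:p\.)?([A-Z][a-z]{2}|[A-Z])(\d+)([A-Z][a-z]{2}|[A-Z])$")


def parse_variant(variant: str) -> tuple[str, int, str]:
    """Parse ``G61E`` or ``p.Gly61Glu`` into (ref, position, alt)."""
    m = _VARIANT_RE.match(variant.strip())
    if not m:
        raise ValueError(f"unparseable variant string {variant!r}")
    ref, pos, alt = m.groups()
    if len(ref) == 3:
        if ref not in _AA3_TO_1:
            raise ValueError(f"unknown residue code {ref!r} in {variant!r}")
        ref = _AA3_TO_1[ref]
    if len(alt) == 3:
        if alt not in _AA3_TO_1:
            raise ValueError(f"unknown residue code {alt!r} in {variant!r}")
        alt = _AA3_TO_1[alt]
    return ref, int(pos), alt


def read_alphamissense_table(path: str | Path, protein_id: str,
                             sequence: ProteinSequence | None = None
                             ) -> VariantScoreTable:
    """Read an AlphaMissense UniProt-substitution TSV filtered to one protein."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"uniprot_id", "protein_variant", "am_pathogenicity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"AlphaMissense table missing columns {sorted(missing)}")
    df = df[df["uniprot_id"] == protein_id]
    parsed = [parse_variant(v) for v in df["protein_variant"]]
    entries = pd.DataFrame({
        "pos": [p for _, p, _ in parsed],
        "ref": [r for r, _, _ in parsed],
        "alt": [a for _, _, a in parsed],
        "score": pd.to_numeric(df["am_pathogenicity"].to_numpy(),
                               errors="raise"),
        "class_label": df.get("am_class", pd.Series(dtype=str)).to_numpy()
        if "am_class" in df.columns else None,
    })
    table = VariantScoreTable(protein_id, entries)
    if sequence is not None:
        table.attach_sequence(sequence)
    return table


def write_alphamissense_table(table: VariantScoreTable, path: str | Path) -> None:
    df = table.entries
    out = pd.DataFrame({
        "uniprot_id": table.protein_id,
        "protein_variant": df["ref"] + df["pos"].astype(str) + df["alt"],
        "am_pathogenicity": df["score"],
        "am_class": df["class_label"],
    })
    with open(path, "w") as fh:
        fh.write("# per-variant missense pathogenicity scores\n")
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Disorder profile CSV

def _check_contiguous(idx: np.ndarray) -> None:
    expected = 1
    for value in idx:
        if value == expected:
            expected += 1
        elif value < expected:
            raise ValueError(f"duplicate residue index {value}")
        else:
            raise ValueError(f"gap at {expected} in residue index column")


def read_disorder_csv(path: str | Path, protein_id: str = "",
                      allow_missing: bool = True) -> list[PerResidueTrack]:
    """Read a per-residue disorder CSV into one track per predictor column."""
    df = pd.read_csv(path, comment="#", dtype=str)
    if "res_index" not in df.columns or "res" not in df.columns:
        raise ValueError("disorder CSV needs 'res_index' and 'res' columns")
    if len(df) == 0:
        raise ValueError("empty disorder profile")
    idx = pd.to_numeric(df["res_index"], errors="raise").to_numpy(dtype=int)
    _check_contiguous(idx)
    predictors = [c for c in df.columns if c not in ("res_index", "res")]
    if not predictors:
        raise ValueError("disorder CSV has no predictor columns")
    tracks = []
    for name in predictors:
        raw = df[name].astype(str).str.strip()
        missing = raw.str.lower().isin(_MISSING_TOKENS)
        if missing.any() and not allow_missing:
            raise ValueError(f"missing score in column {name!r}")
        values = pd.to_numeric(raw.where(~missing), errors="raise").to_numpy(float)
        tracks.append(PerResidueTrack(protein_id, name, values).check_range(0, 1))
    return tracks


def write_disorder_csv(sequence: ProteinSequence,
                       tracks: list[PerResidueTrack],
                       path: str | Path) -> None:
    data = {"res_index": np.arange(1, sequence.length + 1),
            "res": list(sequence.residues)}
    for t in tracks:
        if len(t) != sequence.length:
            raise ValueError(f"track {t.name!r} length != sequence length")
        data[t.name] = t.values
    pd.DataFrame(data).to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# FuzDrop-style droplet-promoting probability profile

_PLLPS_RE = re.compile(r"^#\s*pLLPS\s*=\s*([0-9.eE+-]+)\s*$")


def read_fuzdrop_profile(path: str | Path,
                         protein_id: str = "") -> tuple[PerResidueTrack, float]:
    """Read per-residue droplet-promoting probabilities plus overall pLLPS.

    The protein-level pLLPS is carried on a ``# pLLPS=<x>`` header line.
    """
    pllps = None
    body_lines = []
    with open(path) as fh:
        for line in fh:
            m = _PLLPS_RE.match(line)
            if m:
                pllps = float(m.group(1))
            elif not line.startswith("#"):
                body_lines.append(line)
    if pllps is None:
        raise ValueError("missing '# pLLPS=' header line")
    if not 0.0 <= pllps <= 1.0:
        raise ValueError(f"pLLPS {pllps} outside [0, 1]")
    df = pd.read_csv(StringIO("".join(body_lines)))
    if len(df) == 0:
        raise ValueError("empty profile")
    if "p_DP" not in df.columns:
        raise ValueError("profile needs a 'p_DP' column")
    _check_contiguous(df["res_index"].to_numpy(dtype=int))
    track = PerResidueTrack(protein_id, "p_DP",
                            df["p_DP"].to_numpy(float)).check_range(0, 1)
    return track, pllps


def write_fuzdrop_profile(track: PerResidueTrack, pllps: float,
                          path: str | Path,
                          sequence: ProteinSequence | None = None) -> None:
    if not 0.0 <= pllps <= 1.0:
        raise ValueError(f"pLLPS {pllps} outside [0, 1]")
    res = list(sequence.residues) if sequence is not None else ["X"] * len(track)
    df = pd.DataFrame({"res_index": np.arange(1, len(track) + 1),
                       "res": res, "p_DP": track.values})
    with open(path, "w") as fh:
        fh.write(f"# pLLPS={pllps}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# STRING-style edge list

def read_string_edges(path: str | Path, min_score: float = 0.900) -> nx.Graph:
    """Read a weighted edge list, keeping edges with score >= min_score*1000.

    Scores are on STRING's 0-1000 integer scale; ``min_score`` uses the 0-1
    confidence convention.  Duplicate undirected edges collapse to the
    maximum weight; self-loops are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    graph = nx.Graph()
    if len(df) == 0:
        return graph
    required = {"node1", "node2", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge list missing columns {sorted(missing)}")
    cutoff = min_score * 1000.0
    for node1, node2, score in df[["node1", "node2", "combined_score"]].itertuples(index=False):
        score = float(score)
        if not 0 <= score <= 1000:
            raise ValueError(f"combined_score {score} outside [0, 1000]")
        if node1 == node2:
            logger.warning("dropping self-loop on %s", node1)
            continue
        if score < cutoff:
            continue
        if graph.has_edge(node1, node2):
            graph[node1][node2]["weight"] = max(graph[node1][node2]["weight"], score)
        else:
            graph.add_edge(node1, node2, weight=score)
    return graph


def write_string_edges(graph: nx.Graph, path: str | Path) -> None:
    rows = [(u, v, int(d.get("weight", 1000)))
            for u, v, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["node1", "node2", "combined_score"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Structures

def _single_polymer_chain(structure: gemmi.Structure,
                          chain: str | None) -> gemmi.Chain:
    model = structure[0]
    if len(model) == 0:
        raise ValueError("structure has no chains")
    if chain is not None:
        for ch in model:
            if ch.name == chain:
                return ch
        raise ValueError(f"chain {chain!r} not found")
    if len(model) > 1:
        names = [ch.name for ch in model]
        raise ValueError(f"ambiguous chain: structure has {names}; pass a selector")
    return model[0]


def read_structure_bfactor_track(path: str | Path,
                                 chain: str | None = None) -> PerResidueTrack:
    """Per-residue B-factor (pLDDT in AlphaFold models) of one chain.

    The representative atom is CA, falling back to the first atom of the
    residue.
    """
    structure = gemmi.read_structure(str(path))
    ch = _single_polymer_chain(structure, chain)
    values = []
    for residue in ch:
        atom = residue.find_atom("CA", "*")
        if atom is None:
            atom = residue[0]
        values.append(atom.b_iso)
    if not values:
        raise ValueError("selected chain has no residues")
    return PerResidueTrack(structure.name or "", "pLDDT", np.array(values))


def write_painted_structure(path_in: str | Path, track: PerResidueTrack,
                            path_out: str | Path,
                            chain: str | None = None) -> None:
    """Copy a structure, replacing every atom's B-factor with the residue's
    track value scaled to 0-100 (two-decimal fixed format in PDB output).

    Residues with a missing track value are painted 0.00 and logged.
    """
    track.check_range(0, 1)
    structure = gemmi.read_structure(str(path_in))
    ch = _single_polymer_chain(structure, chain)
    if len(ch) != len(track):
        raise ValueError(
            f"length mismatch: structure chain has {len(ch)} residues, "
            f"track has {len(track)}")
    for residue, value in zip(ch, track.values):
        if math.isnan(value):
            logger.warning("missing track value at residue %s; painting 0.00",
                           residue.seqid.num)
            value = 0.0
        painted = round(value * 100.0, 2)
        for atom in residue:
            atom.b_iso = painted
    out = str(path_out)
    if out.endswith((".cif", ".mmcif")):
        structure.make_mmcif_document().write_file(out)
    else:
        structure.write_pdb(out)
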