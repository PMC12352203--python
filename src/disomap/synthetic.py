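"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of the real inputs: a
smooth latent disorder profile shared between the pseudo-predictor tracks
and the variant scores (so the planted disorder-pathogenicity coupling is
exact at the latent level, with noise entering only at observation
level); droplet-promoting probability tracks with planted above-threshold
segments; and uniform random interaction graphs with fixed node and edge
counts.

One global seed fans out to named substreams, so adding a generator never
perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (STANDARD_AMINO_ACIDS, PerResidueTrack, ProteinSequence,
                        VariantScoreTable)
from .pathogenicity import AMBIGUOUS, BENIGN_CUTOFF, LIKELY_BENIGN, \
    LIKELY_PATHOGENIC, PATHOGENIC_CUTOFF

_AA = np.array(list(STANDARD_AMINO_ACIDS))


@dataclass
class SimulationConfig:
    """Study-scale defaults: a 543-residue protein scored by six disorder
    predictors, with all 19 substitutions per residue and a planted
    exponential decay of pathogenicity against disorder."""

    length: int = 543
    n_predictors: int = 6
    decay_params: tuple[float, float, float] = (0.6, 4.0, 0.2)
    variant_noise_sd: float = 0.1
    predictor_noise_sd: float = 0.05
    smoothness: int = 21                 # moving-average window of the latent walk
    planted_dprs: tuple[tuple[int, int], ...] = ((1, 14), (295, 322), (367, 377))
    composition: np.ndarray | None = None  # default: uniform over the 20 codes
    pllps: float = 0.3692
    graph_spec: tuple[int, int] = (56, 268)
    seed: int = 0
    protein_id: str = "SYN0001"

    def __post_init__(self) -> None:
        a, b, c = self.decay_params
        if min(self.variant_noise_sd, self.predictor_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if b < 0:
            raise ValueError("decay rate must be >= 0")
        for s, e in self.planted_dprs:
            if not 1 <= s <= e <= self.length:
                raise ValueError(f"planted interval ({s}, {e}) outside sequence")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream: stable under addition of other generators."""
        tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng([self.seed, tag])


def gen_sequence(config: SimulationConfig) -> ProteinSequence:
    """Residues drawn i.i.d. from the configured composition."""
    comp = config.composition
    if comp is None:
        comp = np.full(20, 0.05)
    comp = np.asarray(comp, dtype=float)
    if comp.shape != (20,) or comp.min() < 0 or not np.isclose(comp.sum(), 1.0):
        raise ValueError("composition must be 20 non-negative frequencies summing to 1")
    rng = config.rng("sequence")
    residues = rng.choice(_AA, size=config.length, p=comp / comp.sum())
    return ProteinSequence(config.protein_id, "".join(residues))


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


def gen_latent_disorder(config: SimulationConfig) -> PerResidueTrack:
    """Smoothed Gaussian walk squashed to [0, 1] by a logistic map."""
    rng = config.rng("latent")
    walk = np.cumsum(rng.normal(size=config.length))
    smooth = _smooth(walk, config.smoothness)
    z = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
    latent = 1.0 / (1.0 + np.exp(-1.5 * z))
    return PerResidueTrack(config.protein_id, "latent_disorder", latent)


def gen_disorder_tracks(config: SimulationConfig
                        ) -> tuple[PerResidueTrack, list[PerResidueTrack]]:
    """Latent profile plus noisy pseudo-predictor observations of it."""
    if config.n_predictors < 1:
        raise ValueError("need at least one predictor")
    latent = gen_latent_disorder(config)
    rng = config.rng("predictors")
    tracks = []
    for k in range(config.n_predictors):
        noise = rng.normal(0.0, config.predictor_noise_sd, size=config.length)
        values = np.clip(latent.values + noise, 0.0, 1.0)
        tracks.append(PerResidueTrack(config.protein_id, f"pred_{k + 1}", values))
    return latent, tracks


def _class_labels(scores: np.ndarray) -> np.ndarray:
    return np.select([scores < BENIGN_CUTOFF, scores <= PATHOGENIC_CUTOFF],
                     [LIKELY_BENIGN, AMBIGUOUS], default=LIKELY_PATHOGENIC)


def gen_pathogenicity(config: SimulationConfig, latent: PerResidueTrack,
                      seq: ProteinSequence) -> VariantScoreTable:
    """All 19 substitutions per residue, scored from the planted decay.

    score = clip_0^1( a*exp(-b*latent_i) + c + N(0, variant_noise_sd) ).
    """
    a, b, c = config.decay_params
    rng = config.rng("variants")
    base = a * np.exp(-b * latent.values) + c
    noise = rng.normal(0.0, config.variant_noise_sd, size=(config.length, 19))
    scores = np.clip(base[:, None] + noise, 0.0, 1.0)
    pos = np.repeat(np.arange(1, config.length + 1), 19)
    refs = np.repeat(list(seq.residues), 19)
    alts = np.concatenate([
        _AA[_AA != ref] if ref in STANDARD_AMINO_ACIDS else _AA[:19]
        for ref in seq.residues])
    flat = scores.ravel()
    entries = pd.DataFrame({"pos": pos, "ref": refs, "alt": alts,
                            "score": flat, "class_label": _class_labels(flat)})
    return VariantScoreTable(config.protein_id, entries)


def gen_pdp(config: SimulationConfig) -> tuple[PerResidueTrack, float]:
    """Droplet-promoting probability track with planted DPR segments.

    Inside planted intervals p_DP ~ 0.60 + U(0, 0.35); outside
    p_DP ~ U(0, 0.55), capped safely below the 0.60 threshold so the
    planted segments are recovered exactly.
    """
    intervals = sorted(config.planted_dprs)
    for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise ValueError("planted intervals overlap")
    rng = config.rng("pdp")
    values = rng.uniform(0.0, 0.55, size=config.length)
    for s, e in intervals:
        values[s - 1:e] = 0.60 + rng.uniform(0.0, 0.35, size=e - s + 1)
    track = PerResidueTrack(config.protein_id, "p_DP", values)
    return track, config.pllps


def gen_graph(config: SimulationConfig) -> nx.Graph:
    """Uniform random simple graph with exact node/edge counts; weights
    on STRING's high-confidence scale (>= 900)."""
    n, m = config.graph_spec
    if m > n * (n - 1) // 2:
        raise ValueError(f"{m} edges infeasible for {n} nodes "
                         f"(max {n * (n - 1) // 2})")
    rng = config.rng("graph")
    graph = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
    graph = nx.relabel_nodes(graph, {i: f"N{i:03d}" for i in graph.nodes})
    weights = rng.integers(900, 1001, size=m)
    for (u, v), w in zip(graph.edges, weights):
        graph[u][v]["weight"] = int(w)
    return graph


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces, plus the planted truth."""

    config: SimulationConfig
    sequence: ProteinSequence
    latent: PerResidueTrack
    disorder_tracks: list[PerResidueTrack]
    variants: VariantScoreTable
    p_dp: PerResidueTrack
    pllps: float
    graph: nx.Graph
    truth: dict = field(default_factory=dict)


def generate_bundle(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SyntheticBundle:
    """Generate all inputs of one synthetic study under a single seed."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    seq = gen_sequence(config)
    latent, tracks = gen_disorder_tracks(config)
    variants = gen_pathogenicity(config, latent, seq)
    p_dp, pllps = gen_pdp(config)
    graph = gen_graph(config)
    a, b, c = config.decay_params
    return SyntheticBundle(
        config=config, sequence=seq, latent=latent, disorder_tracks=tracks,
        variants=variants, p_dp=p_dp, pllps=pllps, graph=graph,
        truth={"a": a, "b": b, "c": c,
               "planted_dprs": list(config.planted_dprs)})


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, str]:
    """Write the bundle in the exact file dialects the readers consume."""
    from pathlib import Path

    from . import io_formats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequence": out / "protein.fasta",
        "am_table": out / "variants.tsv",
        "disorder_csv": out / "disorder.csv",
        "fuzdrop": out / "fuzdrop.csv",
        "string_edges": out / "string_edges.tsv",
    }
    io_formats.write_fasta(bundle.sequence, paths["sequence"])
    io_formats.write_alphamissense_table(bundle.variants, paths["am_table"])
    io_formats.write_disorder_csv(bundle.sequence, bundle.disorder_tracks,
                                  paths["disorder_csv"])
    io_formats.write_fuzdrop_profile(bundle.p_dp, bundle.pllps,
                                     paths["fuzdrop"], bundle.sequence)
    io_formats.write_string_edges(bundle.graph, paths["string_edges"])
    return {k: str(v) for k, v in paths.items()}
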