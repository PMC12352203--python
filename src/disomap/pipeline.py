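"""End-to-end pipeline: configuration, stage orchestration, reporting.

Stages run on whatever inputs are configured; absent optional inputs skip
their stage with a logged notice.  The JSON report is deterministic given
identical inputs, configuration and seed (no timestamps inside the
report), and a manifest with input checksums is written alongside it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import composition as comp
from . import correlation, disorder, io_formats, network, pathogenicity, phase

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs (any may be None; stages needing them are skipped)
    sequence: str | None = None
    am_table: str | None = None
    disorder_csv: str | None = None
    fuzdrop: str | None = None
    string_edges: str | None = None
    structure: str | None = None
    background: str | None = None
    protein_id: str | None = None

    # thresholds
    disorder_threshold: float = 0.5
    am_benign: float = 0.34
    am_pathogenic: float = 0.564
    pllps_threshold: float = 0.60
    string_min_score: float = 0.900
    dpr_min_length: int = 5
    window: int = 10

    out_dir: str = "disomap_out"
    seed: int = 0
    log_level: str = "INFO"


def validate_config(config: PipelineConfig) -> list[str]:
    """All violated invariants at once; an empty list means valid."""
    errors = []
    for name in ("disorder_threshold", "am_benign", "am_pathogenic",
                 "pllps_threshold", "string_min_score"):
        value = getattr(config, name)
        if not 0.0 <= value <= 1.0:
            errors.append(f"{name} = {value} outside [0, 1]")
    if config.am_benign > config.am_pathogenic:
        errors.append(
            f"am_benign ({config.am_benign}) must not exceed "
            f"am_pathogenic ({config.am_pathogenic})")
    if config.window < 1:
        errors.append(f"window = {config.window} must be >= 1")
    if config.dpr_min_length < 1:
        errors.append(f"dpr_min_length = {config.dpr_min_length} must be >= 1")
    if config.seed < 0:
        errors.append("seed must be non-negative")
    for name in ("sequence", "am_table", "disorder_csv", "fuzdrop",
                 "string_edges", "structure", "background"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            errors.append(f"{name} file not found: {path}")
    return errors


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are present; write report and CSVs.

    Returns the report dict (also written to ``<out_dir>/report.json``).
    Stage failures raise, naming the stage.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": 1, "stages": {}}
    stages = report["stages"]

    seq = None
    mdp = None
    path_mean_track = None
    idpr_regions = None

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            if result is not None:
                stages[name] = result
            return result
        return wrap

    if config.sequence:
        rec = io_formats.read_fasta(config.sequence)
        seq = rec
        stages["sequence"] = {"id": rec.id, "length": rec.length}
    else:
        logger.info("no sequence input; sequence-dependent stages limited")

    # --- disorder ---------------------------------------------------------
    if config.disorder_csv:
        @stage("disorder")
        def _disorder():
            nonlocal mdp, idpr_regions
            tracks = io_formats.read_disorder_csv(
                config.disorder_csv, config.protein_id or (seq.id if seq else ""))
            mdp_track, sd_track = disorder.compute_mdp(tracks)
            mdp = mdp_track
            summary = disorder.summarize_disorder(tracks,
                                                  config.disorder_threshold)
            idpr_regions = disorder.extract_regions(
                mdp_track, config.disorder_threshold, kind="IDPR")
            if seq is not None and seq.length == len(mdp_track):
                io_formats.write_disorder_csv(
                    seq, tracks + [mdp_track, sd_track], out / "disorder_profile.csv")
            idpr_regions.to_frame().to_csv(out / "idpr_regions.csv", index=False)
            return {
                "ppdr_by_predictor": summary.ppdr_by_predictor,
                "ppdr_mdp": summary.ppdr_mdp,
                "category_by_predictor": summary.category_by_predictor,
                "category_mdp": summary.category_mdp,
                "n_idprs": len(idpr_regions),
            }
    else:
        logger.info("disorder stage skipped (no disorder_csv)")

    # --- pathogenicity ----------------------------------------------------
    if config.am_table and seq is not None:
        @stage("pathogenicity")
        def _pathogenicity():
            nonlocal path_mean_track
            table = io_formats.read_alphamissense_table(
                config.am_table, config.protein_id or seq.id, seq)
            path_mean_track = pathogenicity.per_residue_mean(table, seq.length)
            means = pathogenicity.protein_mean_report(table, seq.length)
            per_res = path_mean_track.values
            classes = [pathogenicity.classify_score(v) if not np.isnan(v) else None
                       for v in per_res]
            import pandas as pd
            pd.DataFrame({
                "res_index": np.arange(1, seq.length + 1),
                "res": list(seq.residues),
                "mean_pathogenicity": per_res,
                "class_of_mean": classes,
            }).to_csv(out / "pathogenicity_per_residue.csv", index=False)
            return {"n_variants": len(table), **means}
    else:
        logger.info("pathogenicity stage skipped (needs am_table and sequence)")

    # --- correlation ------------------------------------------------------
    if mdp is not None and path_mean_track is not None:
        @stage("correlation")
        def _correlation():
            fit, paired = correlation.correlate_disorder_pathogenicity(
                mdp, path_mean_track, window=config.window)
            paired.to_csv(out / "correlation_pairs.csv", index=False)
            return {"a": fit.a, "b": fit.b, "c": fit.c,
                    "r_squared": fit.r_squared, "n": fit.n,
                    "converged": fit.converged, "window": config.window}
    else:
        logger.info("correlation stage skipped (needs disorder and pathogenicity)")

    # --- phase separation -------------------------------------------------
    if config.fuzdrop:
        @stage("phase")
        def _phase():
            track, pllps = io_formats.read_fuzdrop_profile(
                config.fuzdrop, config.protein_id or (seq.id if seq else ""))
            dprs = phase.extract_dprs(track, config.pllps_threshold,
                                      config.dpr_min_length)
            call = phase.classify_llps(pllps, dprs)
            dprs.to_frame().to_csv(out / "dpr_regions.csv", index=False)
            result = {"pllps": pllps, "classification": call.classification,
                      "n_dprs": len(dprs),
                      "dprs": [[r.start, r.end] for r in dprs]}
            if idpr_regions is not None and len(idpr_regions):
                overlaps = phase.annotate_overlaps(dprs, idpr_regions)
                overlaps.to_csv(out / "dpr_idpr_overlaps.tsv", sep="\t",
                                index=False)
                result["n_dpr_idpr_overlaps"] = len(overlaps)
            return result
    else:
        logger.info("phase stage skipped (no fuzdrop profile)")

    # --- composition ------------------------------------------------------
    if seq is not None:
        @stage("composition")
        def _composition():
            background = comp.load_background(config.background)
            result = comp.composition_significance(seq, background,
                                                   seed=config.seed)
            ordered = comp.order_by_topidp(result)
            ordered.to_csv(out / "composition.csv", index_label="code")
            significant = ordered[ordered["significant"]]
            return {
                "n_significant": int(ordered["significant"].sum()),
                "enriched": sorted(significant[significant["frac_diff"] > 0].index),
                "depleted": sorted(significant[significant["frac_diff"] < 0].index),
            }
    else:
        logger.info("composition stage skipped (no sequence)")

    # --- network ----------------------------------------------------------
    if config.string_edges:
        @stage("network")
        def _network():
            graph = io_formats.read_string_edges(config.string_edges,
                                                 config.string_min_score)
            if graph.number_of_nodes() == 0:
                return {"n_nodes": 0, "n_edges": 0}
            summary = network.summarize(graph)
            return dataclasses.asdict(summary)
    else:
        logger.info("network stage skipped (no string_edges)")

    # --- structure painting ----------------------------------------------
    if config.structure and path_mean_track is not None:
        @stage("paint")
        def _paint():
            suffix = Path(config.structure).suffix or ".pdb"
            painted = out / f"painted_pathogenicity{suffix}"
            io_formats.write_painted_structure(config.structure,
                                               path_mean_track, painted)
            return {"painted_structure": painted.name}
    else:
        logger.info("paint stage skipped (needs structure and pathogenicity)")

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")

    manifest = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "input_checksums": {
            name: _sha256(path)
            for name in ("sequence", "am_table", "disorder_csv", "fuzdrop",
                         "string_edges", "structure", "background")
            if (path := getattr(config, name)) is not None
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
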