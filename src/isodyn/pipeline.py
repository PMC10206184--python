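"""End-to-end analysis driver.

Runs the full desk-scale analysis over a set of named conformer
trajectories: per-conformer RMSD/RMSF and equilibrium diagnostics, the
cross-conformer percent-of-total movement table, region scores and stability
ranking, the cross-correlation matrix and thresholded pair lists for a
designated long trajectory, optional conservation scoring with B-factor
painting, and a machine-readable manifest with SHA-256 checksums of every
output so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .conservation import (
    assign_categories,
    category_bfactors,
    column_match_fractions,
    parse_alignment,
    profile_to_tsv,
)
from .dynamics import (
    AnalysisConfig,
    RegionDefinition,
    compute_dccm,
    equilibrium_diagnostics,
    extract_correlated_pairs,
    pairs_to_tsv,
    percent_total_movement,
    rank_conformers,
    region_movement_score,
    rmsd_series,
    rmsf_profile,
)
from .structure import Trajectory, read_trajectory, write_bfactor_annotation

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    ``trajectories`` maps conformer names to multi-model PDB paths or
    in-memory :class:`Trajectory` objects.  ``long_conformer`` selects the
    trajectory used for the correlation matrix and pair extraction.
    """

    trajectories: Mapping[str, "str | Path | Trajectory"]
    out_dir: Path
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    regions: Mapping[str, RegionDefinition] = field(default_factory=dict)
    rank_by_region: str = "PBR"
    long_conformer: str | None = None
    alignment_path: Path | None = None
    alignment_text: str | None = None
    alignment_reference_id: str | None = None
    conservation_chain: str = "R"
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(message: str) -> None:
    print(f"[isodyn] {message}", file=sys.stderr)


def _load_trajectory(name: str, source) -> Trajectory:
    if isinstance(source, Trajectory):
        t = source
        t.name = name
        return t
    path = Path(source)
    if not path.exists():
        raise PipelineError(f"stage load: trajectory file {path} for {name!r} not found")
    return read_trajectory(path.read_text(), name=name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Output is a pure function of (inputs, configuration, seed): all files
    use fixed-precision text formatting, so identical reruns produce
    identical checksums.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": {"name": "isodyn", "version": __version__, "numpy": np.__version__},
        "seed": config.seed,
        "parameters": {
            "dccm_threshold": config.analysis.dccm_threshold,
            "threshold_mode": config.analysis.threshold_mode,
            "strict_threshold": config.analysis.strict_threshold,
            "high_threshold": config.analysis.high_threshold,
            "capture_interval_ps": config.analysis.capture_interval_ps,
            "equil_blocks": config.analysis.equil_blocks,
            "rank_by_region": config.rank_by_region,
        },
        "inputs": {name: str(src) if not isinstance(src, Trajectory) else "<in-memory>"
                   for name, src in config.trajectories.items()},
        "outputs": {},
        "complete": False,
    }
    names = list(config.trajectories)
    if len(set(names)) != len(names):
        raise PipelineError("stage config: conformer names must be unique")
    # fail fast on missing files before any computation
    for name, src in config.trajectories.items():
        if not isinstance(src, Trajectory) and not Path(src).exists():
            raise PipelineError(f"stage config: trajectory file {src} for {name!r} not found")
    if config.alignment_path is not None and not Path(config.alignment_path).exists():
        raise PipelineError(f"stage config: alignment file {config.alignment_path} not found")

    def emit(key: str, filename: str, text: str, description: str) -> None:
        path = out_dir / filename
        path.write_text(text)
        manifest["outputs"][key] = {
            "file": filename,
            "sha256": _sha256(path),
            "description": description,
        }

    try:
        profiles = []
        for name, src in config.trajectories.items():
            t0 = time.time()
            traj = _load_trajectory(name, src)
            series = rmsd_series(traj, config.analysis)
            emit(
                f"rmsd:{name}", f"rmsd_{name}.tsv", series.to_tsv(),
                f"per-frame Ca RMSD (A) for conformer {name}",
            )
            profile = rmsf_profile(traj, config.analysis)
            profiles.append(profile)
            emit(
                f"rmsf:{name}", f"rmsf_{name}.tsv", profile.to_tsv(),
                f"per-residue Ca RMSF (A) for conformer {name}",
            )
            equil = equilibrium_diagnostics({"rmsd": series.values}, config.analysis)
            emit(
                f"equil:{name}", f"equil_{name}.tsv", equil.to_tsv(),
                f"block-mean equilibrium diagnostics for conformer {name}",
            )
            _log(f"conformer {name}: {traj.n_frames} frames analyzed "
                 f"in {time.time() - t0:.1f} s")
    except (ValueError, OSError) as exc:
        raise PipelineError(f"stage per-conformer statistics: {exc}") from exc

    try:
        if len(profiles) >= 2:
            table = percent_total_movement(profiles)
            emit(
                "percent_table", "percent_movement.tsv",
                table.to_csv(sep="\t", float_format="%.4f"),
                "percent-of-total movement per residue across conformers",
            )
        scores = []
        for profile in profiles:
            for region in config.regions.values():
                scores.append(region_movement_score(profile, region))
        if scores:
            lines = ["conformer\tregion\tsummed_rmsf_A"]
            for s in scores:
                lines.append(f"{s.conformer}\t{s.region}\t{s.score:.6f}")
            emit(
                "region_scores", "region_scores.tsv", "\n".join(lines) + "\n",
                "summed RMSF per named region per conformer",
            )
            if config.rank_by_region in config.regions:
                ranking = rank_conformers(scores, config.rank_by_region)
                emit(
                    "ranking", "ranking.tsv",
                    "rank\tconformer\n"
                    + "\n".join(f"{i + 1}\t{c}" for i, c in enumerate(ranking)) + "\n",
                    f"conformers ranked by ascending {config.rank_by_region} movement "
                    f"(most stable first)",
                )
    except (ValueError, OSError) as exc:
        raise PipelineError(f"stage cross-conformer statistics: {exc}") from exc

    try:
        long_name = config.long_conformer or names[0]
        long_traj = _load_trajectory(long_name, config.trajectories[long_name])
        dccm = compute_dccm(long_traj, config.analysis)
        emit(
            "dccm", "dccm.tsv", dccm.to_tsv(),
            f"residue-residue cross-correlation matrix for conformer {long_name}",
        )
        region_list = list(config.regions.values())
        if len(region_list) >= 2 and region_list[0].chain == region_list[1].chain:
            pairs = extract_correlated_pairs(
                dccm, config.analysis, scope="intra_pair_of_regions",
                regions=(region_list[0], region_list[1]),
            )
            emit(
                "pairs_regions", "pairs_regions.tsv", pairs_to_tsv(pairs),
                f"supra-threshold {region_list[0].name}x{region_list[1].name} pairs",
            )
        inter = extract_correlated_pairs(dccm, config.analysis, scope="inter_chain")
        emit(
            "pairs_interchain", "pairs_interchain.tsv", pairs_to_tsv(inter),
            "supra-threshold inter-chain pairs",
        )
    except (ValueError, OSError) as exc:
        raise PipelineError(f"stage correlation analysis: {exc}") from exc

    try:
        alignment_text = config.alignment_text
        if alignment_text is None and config.alignment_path is not None:
            alignment_text = Path(config.alignment_path).read_text()
        if alignment_text is not None:
            msa = parse_alignment(alignment_text, config.alignment_reference_id)
            profile = assign_categories(
                column_match_fractions(msa),
                strict_threshold=config.analysis.strict_threshold,
                high_threshold=config.analysis.high_threshold,
            )
            emit(
                "conservation", "conservation.tsv", profile_to_tsv(profile),
                "per-reference-position conservation profile",
            )
            long_top = _load_trajectory(
                long_name, config.trajectories[long_name]
            ).topology
            values = category_bfactors(profile, config.conservation_chain)
            painted = write_bfactor_annotation(long_top, values, fill_value=0.0)
            emit(
                "conservation_pdb", "conservation_painted.pdb", painted,
                "structure with conservation categories in the B-factor column",
            )
    except (ValueError, OSError) as exc:
        raise PipelineError(f"stage conservation: {exc}") from exc

    manifest["complete"] = True
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    _log(f"pipeline complete: {len(manifest['outputs'])} outputs in {out_dir}")
    return manifest
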