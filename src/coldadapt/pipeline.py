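"""Configuration-driven orchestration of a two-system comparison.

The pipeline mirrors the analysis order used for replicated MD studies:
replicate-sampling assessment first (RMSIP/CES/DRES, with outlier replicates
*flagged*, never silently removed), then flexibility profiling, structure
networks, and sequence comparison.  The configuration is a versioned YAML
schema; unknown keys are errors.  Every text artifact carries the config
hash and seed in a header comment, and a manifest records all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import flexibility as flex
from . import psn as psnmod
from . import seqadapt
from . import similarity as sim
from .core import Ensemble, ReplicateSet, read_ensemble, superpose_frames

logger = logging.getLogger("coldadapt")

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "generate_report"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnsembleEntry(_Strict):
    path: str
    replicate_id: str


class SystemConfig(_Strict):
    id: str
    ensembles: list[EnsembleEntry]
    frame_interval_ns: float = 0.02


class SimilarityStage(_Strict):
    enabled: bool = True
    metrics: list[str] = Field(default_factory=lambda: ["rmsip", "ces"])
    components: int = 10
    preference: float = -10.0
    dim: int = 6
    max_pooled: int = 3000
    outlier_jsd_threshold: float = 0.5


class FlexibilityStage(_Strict):
    enabled: bool = True
    window_ns: float = 10.0
    exclude_initial_ns: float = 10.0
    selection: str = "calpha"


class PsnStage(_Strict):
    enabled: bool = True
    classes: list[str] = Field(default_factory=lambda: ["hydrophobic"])
    persistence_threshold: float = 0.2
    exclude_backbone_hbonds: bool = False
    infer_hydrogens: bool = False


class SequenceStage(_Strict):
    enabled: bool = False
    alignment: str | None = None
    labels: str | None = None
    format: str = "fasta"
    target_a: str | None = None
    target_b: str | None = None
    conservation_cutoff: float = 0.8


class StagesConfig(_Strict):
    similarity: SimilarityStage = Field(default_factory=SimilarityStage)
    flexibility: FlexibilityStage = Field(default_factory=FlexibilityStage)
    psn: PsnStage = Field(default_factory=PsnStage)
    sequence: SequenceStage = Field(default_factory=SequenceStage)


class PipelineConfig(_Strict):
    version: int = 1
    seed: int = 0
    output_dir: str = "coldadapt_out"
    systems: list[SystemConfig] = Field(min_length=1)
    stages: StagesConfig = Field(default_factory=StagesConfig)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = PipelineConfig.model_validate(raw)
    base = Path(path).parent
    for system in cfg.systems:
        for entry in system.ensembles:
            p = Path(entry.path)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(
                    f"ensemble path {entry.path!r} (system {system.id}) not found")
            entry.path = str(p)
    return cfg


def _stamp(path: Path, frame: pd.DataFrame, cfg: PipelineConfig,
           index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# coldadapt config={cfg.config_hash()} seed={cfg.seed}\n")
        frame.to_csv(fh, sep="\t", index=index)


def _load_system(system: SystemConfig) -> ReplicateSet:
    ensembles = [
        read_ensemble(e.path, frame_interval=system.frame_interval_ns,
                      replicate_id=e.replicate_id, system_id=system.id)
        for e in system.ensembles
    ]
    return ReplicateSet(system_id=system.id, ensembles=ensembles)


def _similarity_stage(cfg: PipelineConfig, systems: list[ReplicateSet],
                      outdir: Path) -> dict:
    st = cfg.stages.similarity
    artifacts = {}
    for rs in systems:
        fitted = [superpose_frames(e, rs.ensembles[0].frames[0])
                  for e in rs.ensembles]
        flags = {}
        for metric in st.metrics:
            if metric == "rmsip":
                if len(fitted) < 2:
                    continue
                mat = sim.rmsip_matrix(fitted, n_components=st.components)
            elif metric == "ces":
                if len(fitted) < 2:
                    continue
                mat = sim.ces(fitted, preference=st.preference,
                              max_pooled=st.max_pooled)
            elif metric == "dres":
                if len(fitted) < 2:
                    continue
                mat = sim.dres(fitted, dim=st.dim, seed=cfg.seed,
                               max_pooled=st.max_pooled)
            else:
                raise ValueError(f"unknown similarity metric {metric!r}")
            png = outdir / f"similarity_{rs.system_id}_{metric}.png"
            sim.similarity_heatmap(mat, png)
            artifacts[f"{rs.system_id}:{metric}"] = str(png)
            if mat.metric.endswith("_jsd"):
                means = mat.mean_offdiagonal()
                for rid, m in zip(mat.ids, means):
                    if m > st.outlier_jsd_threshold:
                        flags[rid] = max(flags.get(rid, 0.0), float(m))
        if flags:
            for rid, m in flags.items():
                logger.warning(
                    "system %s: replicate %s flagged as sampling outlier "
                    "(mean off-diagonal JSD %.3f > %.3f)",
                    rs.system_id, rid, m, st.outlier_jsd_threshold)
        flag_frame = pd.DataFrame(
            [{"replicate_id": rid, "mean_offdiag_jsd": m} for rid, m in flags.items()]
        ) if flags else pd.DataFrame(columns=["replicate_id", "mean_offdiag_jsd"])
        path = outdir / f"outlier_flags_{rs.system_id}.tsv"
        _stamp(path, flag_frame, cfg)
        artifacts[f"{rs.system_id}:outlier_flags"] = str(path)
    return artifacts


def _flexibility_stage(cfg: PipelineConfig, systems: list[ReplicateSet],
                       outdir: Path) -> dict:
    st = cfg.stages.flexibility
    artifacts = {}
    averaged = {}
    for rs in systems:
        profiles = [
            flex.windowed_rmsf(e, window_ns=st.window_ns,
                               exclude_initial_ns=st.exclude_initial_ns,
                               selection=st.selection)
            for e in rs.ensembles
        ]
        avg = flex.average_profiles(profiles)
        averaged[rs.system_id] = avg
        path = outdir / f"rmsf_{rs.system_id}.tsv"
        _stamp(path, avg.to_frame(), cfg)
        artifacts[f"{rs.system_id}:rmsf"] = str(path)
    if len(systems) >= 2:
        a, b = systems[0].system_id, systems[1].system_id
        diff = flex.rmsf_difference(averaged[a], averaged[b])
        path = outdir / f"rmsf_difference_{a}_minus_{b}.tsv"
        _stamp(path, diff.to_frame(), cfg)
        artifacts["rmsf_difference"] = str(path)
    return artifacts


def _psn_stage(cfg: PipelineConfig, systems: list[ReplicateSet],
               outdir: Path) -> dict:
    st = cfg.stages.psn
    artifacts = {}
    graphs: dict[tuple[str, str], psnmod.PSNGraph] = {}
    for rs in systems:
        pooled = np.concatenate([e.frames for e in rs.ensembles])
        merged = Ensemble(rs.ensembles[0].topology, pooled,
                          rs.ensembles[0].frame_interval,
                          replicate_id="pooled", system_id=rs.system_id)
        for cls in st.classes:
            g = psnmod.build_psn(merged, cls,
                                 persistence_threshold=st.persistence_threshold,
                                 infer_hydrogens=st.infer_hydrogens)
            graphs[(rs.system_id, cls)] = g
            gml = outdir / f"psn_{rs.system_id}_{cls}.graphml"
            g.write_graphml(gml)
            tsv = outdir / f"psn_{rs.system_id}_{cls}_edges.tsv"
            _stamp(tsv, g.edges_to_frame(), cfg)
            hubs = psnmod.find_hubs(g)
            hub_tsv = outdir / f"psn_{rs.system_id}_{cls}_hubs.tsv"
            _stamp(hub_tsv, pd.DataFrame(hubs, columns=["residue", "degree"]), cfg)
            artifacts[f"{rs.system_id}:{cls}:graphml"] = str(gml)
            artifacts[f"{rs.system_id}:{cls}:edges"] = str(tsv)
            artifacts[f"{rs.system_id}:{cls}:hubs"] = str(hub_tsv)
    if len(systems) >= 2:
        a, b = systems[0].system_id, systems[1].system_id
        for cls in st.classes:
            diff = psnmod.diff_networks(
                graphs[(a, cls)], graphs[(b, cls)],
                exclude_mainchain_hbonds=st.exclude_backbone_hbonds)
            rows = (
                [{"set": "only_in_a", "residue_a": e.residue_a,
                  "residue_b": e.residue_b, "persistence": e.persistence}
                 for e in diff.only_in_a]
                + [{"set": "only_in_b", "residue_a": e.residue_a,
                    "residue_b": e.residue_b, "persistence": e.persistence}
                   for e in diff.only_in_b]
                + [{"set": "shared", "residue_a": ea.residue_a,
                    "residue_b": ea.residue_b,
                    "persistence": f"{ea.persistence:g}/{eb.persistence:g}"}
                   for ea, eb in diff.shared]
            )
            path = outdir / f"psn_diff_{cls}_{a}_vs_{b}.tsv"
            _stamp(path, pd.DataFrame(
                rows, columns=["set", "residue_a", "residue_b", "persistence"]), cfg)
            artifacts[f"diff:{cls}"] = str(path)
            counts_path = outdir / f"psn_counts_{cls}_{a}_vs_{b}.tsv"
            _stamp(counts_path, pd.DataFrame([diff.counts]), cfg)
            artifacts[f"counts:{cls}"] = str(counts_path)
    return artifacts


def _sequence_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    st = cfg.stages.sequence
    if not (st.alignment and st.labels and st.target_a and st.target_b):
        raise ValueError(
            "sequence stage enabled but alignment/labels/targets incomplete")
    aln = seqadapt.read_labeled_alignment(st.alignment, st.labels,
                                          st.target_a, st.target_b,
                                          format=st.format)
    comp = seqadapt.composition_delta(aln)
    records = seqadapt.classify_substitutions(
        seqadapt.substitution_sites(aln), aln,
        conservation_cutoff=st.conservation_cutoff)
    artifacts = {}
    comp_path = outdir / "composition.tsv"
    _stamp(comp_path, comp.to_frame(), cfg)
    artifacts["composition"] = str(comp_path)
    rec_path = outdir / "substitutions.tsv"
    _stamp(rec_path, seqadapt.records_to_frame(records), cfg)
    artifacts["substitutions"] = str(rec_path)
    return artifacts


STAGE_ORDER = ("similarity", "flexibility", "psn", "sequence")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns a manifest mapping stage name to
    its artifacts.  A stage failure aborts with the stage name while
    preserving partial outputs already written."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    logger.info("config hash %s, seed %d", config.config_hash(), config.seed)
    needs_data = any([config.stages.similarity.enabled,
                      config.stages.flexibility.enabled,
                      config.stages.psn.enabled])
    systems = [_load_system(s) for s in config.systems] if needs_data else []
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "stages": {}}
    for stage in STAGE_ORDER:
        st_cfg = getattr(config.stages, stage)
        if not st_cfg.enabled:
            continue
        logger.info("stage %s: parameters %s", stage, st_cfg.model_dump())
        try:
            if stage == "similarity":
                artifacts = _similarity_stage(config, systems, outdir)
            elif stage == "flexibility":
                artifacts = _flexibility_stage(config, systems, outdir)
            elif stage == "psn":
                artifacts = _psn_stage(config, systems, outdir)
            else:
                artifacts = _sequence_stage(config, outdir)
        except Exception as exc:
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = artifacts
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def generate_report(outdir) -> Path:
    """Collate stage artifacts from a pipeline output directory into one
    markdown summary (one section per executed stage)."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not outdir.is_dir() or not manifest_path.exists():
        raise FileNotFoundError(f"no pipeline manifest under {outdir}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# coldadapt comparison report",
        "",
        f"config hash: `{manifest['config_hash']}`  |  seed: {manifest['seed']}",
        "",
    ]
    titles = {
        "similarity": "Replicate sampling similarity",
        "flexibility": "Flexibility profiles",
        "psn": "Protein structure networks",
        "sequence": "Sequence comparison",
    }
    for stage in STAGE_ORDER:
        artifacts = manifest.get("stages", {}).get(stage)
        if not artifacts:
            continue
        lines.append(f"## {titles[stage]}")
        lines.append("")
        for key, path in sorted(artifacts.items()):
            p = Path(path)
            lines.append(f"- `{key}`: [{p.name}]({p.name})")
            if p.suffix == ".tsv" and p.exists():
                table = pd.read_csv(p, sep="\t", comment="#")
                if not table.empty:
                    lines.append("")
                    lines.append("  " + table.head(10).to_string(index=False)
                                 .replace("\n", "\n  "))
            lines.append("")
    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return report
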