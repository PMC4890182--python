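"""End-to-end orchestration: simulate -> qc -> dmp -> gsea -> enrich -> overlap.

Each stage writes its artifacts under the output directory and the run
finishes with a manifest JSON listing every artifact with a SHA-256
content hash, so identical seeds yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .datatypes import MethylationDataset, ProbeAnnotation
from .dmp import (
    call_dmps,
    dmp_lists,
    group_dmp_table,
    heterogeneity_summary,
    paired_differences,
)
from .genes import fisher_gsea, gene_binomial_test
from .overlap import contrast_effects, fisher_overlap, top_k_by_delta
from .qc import knn_impute, qc_filter
from .regions import region_enrichment, select_top_probes
from .simulate import SimulationConfig, simulate_dataset, simulate_gene_sets, simulate_peak_tracks

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and stage thresholds of one pipeline run."""

    outdir: str = "dmpipe_out"
    seed: int = 0
    # either a simulation config, or paths to user-supplied inputs
    simulate: SimulationConfig | None = field(default_factory=SimulationConfig)
    beta_path: str | None = None
    detection_p_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    gene_sets_path: str | None = None
    tracks_manifest_path: str | None = None
    # QC / imputation
    sample_min_coverage: float = 0.80
    probe_min_coverage: float = 0.95
    detection_threshold: float = 0.05
    knn_k: int = 5
    # DMP calling
    q_threshold: float = 0.05
    delta_threshold: float = 0.03
    # region enrichment
    enrich_n_probes: int = 1000
    enrich_n_sets: int = 1000
    enrich_q_threshold: float = 0.05
    # overlap
    top_k: int = 5000

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("sample_min_coverage", 0.0, 1.0),
            ("probe_min_coverage", 0.0, 1.0),
            ("detection_threshold", 0.0, 1.0),
            ("q_threshold", 0.0, 1.0),
            ("enrich_q_threshold", 0.0, 1.0),
        ):
            if not (lo <= getattr(self, name) <= hi):
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")
        if self.delta_threshold < 0:
            raise ValueError("delta_threshold must be non-negative")
        if self.simulate is None and (self.beta_path is None or self.samples_path is None):
            raise ValueError("either a simulate config or beta/samples paths are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulate", "default")
        if sim_raw is None:
            sim = None
        elif sim_raw == "default":
            sim = SimulationConfig(seed=int(raw.get("seed", 0)))
        else:
            sim = SimulationConfig(**sim_raw)
        return cls(simulate=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    Any stage failure aborts with the stage named in the exception;
    artifacts already written by earlier stages are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        # ------------------------------------------------ simulate / load
        if config.simulate is not None:
            stage = "simulate"
            dataset, annotation, truth = simulate_dataset(config.simulate)
            tracks = simulate_peak_tracks(annotation, truth, config.simulate)
            gene_sets = simulate_gene_sets(annotation, config.simulate)
            for name, p in dio.write_dataset(dataset, outdir, prefix="sim_").items():
                artifacts[f"sim_{name}"] = p
            artifacts["annotation"] = outdir / "annotation.tsv"
            dio.write_annotation(annotation, artifacts["annotation"])
            artifacts["gene_sets"] = outdir / "gene_sets.gmt"
            dio.write_gmt(gene_sets, artifacts["gene_sets"])
            tracks_dir = outdir / "tracks"
            artifacts["tracks_manifest"] = dio.write_track_set(tracks, tracks_dir)
            artifacts["ground_truth"] = outdir / "ground_truth.json"
            dio.write_ground_truth(truth, artifacts["ground_truth"])
        else:
            stage = "load"
            dataset = dio.read_dataset(
                config.beta_path, config.samples_path, config.detection_p_path
            )
            annotation = dio.read_annotation(config.annotation_path)
            gene_sets = (
                dio.read_gmt(config.gene_sets_path) if config.gene_sets_path else None
            )
            tracks = (
                dio.read_track_set(config.tracks_manifest_path)
                if config.tracks_manifest_path
                else None
            )

        # --------------------------------------------------------------- qc
        stage = "qc"
        dataset = qc_filter(
            dataset,
            sample_min_coverage=config.sample_min_coverage,
            probe_min_coverage=config.probe_min_coverage,
            detection_threshold=config.detection_threshold,
        )
        dataset = knn_impute(dataset, k=config.knn_k, detection_threshold=config.detection_threshold)
        artifacts["qc_beta"] = outdir / "qc_beta.tsv"
        dio.write_matrix(dataset.beta, artifacts["qc_beta"])
        annotation = ProbeAnnotation(table=annotation.table.loc[dataset.beta.index])

        # -------------------------------------------------------------- dmp
        stage = "dmp"
        diffs_mut = paired_differences(dataset, "MUT")
        diffs_ctrl = paired_differences(dataset, "control")
        table_mut = group_dmp_table(diffs_mut)
        table_ctrl = group_dmp_table(diffs_ctrl)
        dmps = call_dmps(
            table_mut,
            table_ctrl,
            q_threshold=config.q_threshold,
            delta_threshold=config.delta_threshold,
        )
        het_summary = None
        if dmps["dmp"].any():
            het_summary, per_probe = heterogeneity_summary(diffs_mut, dmps)
            dmps = dmps.join(per_probe)
        artifacts["dmp_table"] = outdir / "dmp_table.tsv"
        dmps.to_csv(artifacts["dmp_table"], sep="\t", index_label="probe_id", float_format="%.6g")
        hyper, hypo = dmp_lists(dmps)
        artifacts["dmps_hyper"] = outdir / "dmps_hyper.txt"
        artifacts["dmps_hypo"] = outdir / "dmps_hypo.txt"
        dio.write_probe_list(hyper, artifacts["dmps_hyper"])
        dio.write_probe_list(hypo, artifacts["dmps_hypo"])

        # ------------------------------------------------------------- gsea
        stage = "gsea"
        if gene_sets is not None:
            for stratum in ("hyper", "hypo"):
                gene_res = gene_binomial_test(dmps, annotation, stratum)
                artifacts[f"genes_{stratum}"] = outdir / f"genes_{stratum}.tsv"
                gene_res.to_csv(artifacts[f"genes_{stratum}"], sep="\t", index=False, float_format="%.6g")
                sig_genes = set(gene_res.loc[gene_res["significant"], "gene"])
                universe = set(gene_res["gene"])
                gsea_res = fisher_gsea(sig_genes, universe, gene_sets)
                artifacts[f"gsea_{stratum}"] = outdir / f"gsea_{stratum}.tsv"
                gsea_res.to_csv(artifacts[f"gsea_{stratum}"], sep="\t", index=False, float_format="%.6g")

        # ----------------------------------------------------------- enrich
        stage = "enrich"
        if tracks is not None:
            for direction in ("hyper", "hypo"):
                probes = select_top_probes(dmps, n=config.enrich_n_probes, direction=direction)
                if not probes:
                    logger.warning("enrich: no %s probes to test; stage skipped", direction)
                    continue
                enr = region_enrichment(
                    probes,
                    annotation,
                    tracks,
                    n_sets=config.enrich_n_sets,
                    seed=config.seed,
                    q_threshold=config.enrich_q_threshold,
                )
                artifacts[f"enrichment_{direction}"] = outdir / f"enrichment_{direction}.tsv"
                enr.to_csv(artifacts[f"enrichment_{direction}"], sep="\t", index=False, float_format="%.6g")

        # ---------------------------------------------------------- overlap
        stage = "overlap"
        mut_fimb = dataset.beta[
            dataset.samples.loc[
                (dataset.samples["group"] == "MUT") & (dataset.samples["site"] == "fimbrial"),
                "sample_id",
            ]
        ]
        ctrl_fimb = dataset.beta[
            dataset.samples.loc[
                (dataset.samples["group"] == "control") & (dataset.samples["site"] == "fimbrial"),
                "sample_id",
            ]
        ]
        overlap_rows = []
        if mut_fimb.shape[1] and ctrl_fimb.shape[1]:
            carrier_effect = contrast_effects(mut_fimb, ctrl_fimb)
            paired_effect = pd.Series(
                diffs_mut.median(axis=1), index=diffs_mut.index, name="effect"
            )
            k = min(config.top_k, len(carrier_effect))
            if k < config.top_k:
                logger.warning("overlap: top_k clamped to universe size %d", k)
            universe = set(carrier_effect.index)
            for sign in ("increase", "decrease"):
                la = top_k_by_delta(carrier_effect, k=k, sign=sign)
                lb = top_k_by_delta(paired_effect, k=k, sign=sign)
                res = fisher_overlap(
                    la, lb, universe,
                    list_a_name=f"carrier_vs_control_fimbrial_{sign}",
                    list_b_name=f"fimbrial_vs_proximal_mut_{sign}",
                )
                overlap_rows.append(res.to_dict())
            artifacts["overlap"] = outdir / "overlap.tsv"
            pd.DataFrame(overlap_rows).to_csv(artifacts["overlap"], sep="\t", index=False, float_format="%.6g")

        # --------------------------------------------------------- manifest
        stage = "manifest"
        manifest = {
            "config": _config_as_dict(config),
            "heterogeneity": {str(k): v for k, v in (het_summary or {}).items()},
            "artifacts": {
                name: {"path": str(p), "sha256": _sha256(p)} for name, p in artifacts.items()
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _config_as_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
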