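"""End-to-end orchestration: simulate/load → preprocess → DEP → enrichment → MCODE.

A run is configured either by a :class:`~traplfq.simulate.SimConfig` (fully
synthetic) or by paths to a proteinGroups table and design files — exactly
one of the two.  Every stage writes its table under the output directory and
the run closes with a manifest listing each artifact with its SHA-256 hash,
so two runs with the same configuration and seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import lfq_io, preprocess, diffexpr, enrichment, netcluster, simulate

log = logging.getLogger("traplfq")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str
    sim: simulate.SimConfig | None = None
    protein_groups_path: str | None = None
    design_path: str | None = None
    comparisons_path: str | None = None
    gmt_path: str | None = None
    edges_path: str | None = None
    min_frac: float = 0.8
    min_peptides: int = 2
    q_cut: float = 0.05
    z_cut: float = 1.96
    kappa: float = 0.4
    score_threshold: float = 0.4
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    drop_artifacts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.protein_groups_path is None):
            raise ValueError(
                "exactly one of a SimConfig or a proteinGroups path must be given"
            )
        if not (0 < self.min_frac <= 1 and 0 < self.q_cut < 1 and self.z_cut >= 0):
            raise ValueError("threshold out of range")


@dataclass
class RunManifest:
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stage_log: list[dict] = field(default_factory=list)

    def record(self, path: Path) -> None:
        self.files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest.record(path)


def run_all(config: RunConfig) -> RunManifest:
    """Execute every stage in fixed order; abort names the failing stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()

    stage = "input"
    try:
        if config.sim is not None:
            matrix, truth = simulate.simulate_lfq(config.sim)
            design = config.sim.design()
            pg_path = out / "proteinGroups.tsv"
            lfq_io.write_protein_groups(matrix, pg_path)
            manifest.record(pg_path)
            simulate.write_ground_truth(truth, out / "ground_truth.tsv")
            manifest.record(out / "ground_truth.tsv")
        else:
            matrix = lfq_io.read_protein_groups(config.protein_groups_path)
            design = lfq_io.read_design(config.design_path, config.comparisons_path)
        design.validate_against(matrix)
        n_total = matrix.n_proteins
        if config.drop_artifacts:
            matrix = lfq_io.drop_artifacts(matrix)
        log.info("input: %d proteins (%d after artifact removal)",
                 n_total, matrix.n_proteins)
        manifest.stage_log.append(
            {"stage": "input", "n_proteins": n_total,
             "n_after_artifact_removal": matrix.n_proteins}
        )
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError(stage, exc) from exc

    stage = "preprocess"
    try:
        normalized = preprocess.median_normalize(matrix)
        pre = preprocess.impute_noise(normalized)
        preprocess.write_preprocessing_report(pre, out / "preprocess_report.tsv")
        manifest.record(out / "preprocess_report.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    for test, ref in design.comparisons:
        tag = f"{test}_vs_{ref}"
        stage = f"dep[{tag}]"
        try:
            kept, dropped = preprocess.quantifiability_filter(
                pre.matrix, design, (test, ref),
                pre_imputation_missing=pre.pre_imputation_missing,
                min_frac=config.min_frac, min_peptides=config.min_peptides,
            )
            table = diffexpr.dep_table(
                pre, design, (test, ref), kept,
                q_cut=config.q_cut, z_cut=config.z_cut,
            )
            _write_tsv(table, out / f"dep_{tag}.tsv", manifest)
            entry = {
                "stage": stage, "n_total": pre.matrix.n_proteins,
                "n_quantifiable": len(kept), "n_dropped": len(dropped),
                "n_up": table.attrs["n_up"], "n_down": table.attrs["n_down"],
            }
            log.info(
                "%s: %d quantifiable of %d; %d up, %d down (q<%g, |z|>%g)",
                tag, len(kept), pre.matrix.n_proteins,
                entry["n_up"], entry["n_down"], config.q_cut, config.z_cut,
            )
            manifest.stage_log.append(entry)

            deps = set(table.loc[table["call"] != "ns", "protein_id"])
            if config.gmt_path and deps:
                stage = f"enrich[{tag}]"
                catalog = enrichment.read_gmt(config.gmt_path)
                enr = enrichment.enrichment_with_groups(
                    deps, catalog, q_cut=config.q_cut,
                    kappa_threshold=config.kappa,
                )
                _write_tsv(enr, out / f"enrichment_{tag}.tsv", manifest)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if config.edges_path:
        stage = "mcode"
        try:
            ppi = netcluster.load_edges(
                config.edges_path, score_threshold=config.score_threshold
            )
            complexes = netcluster.mcode_complexes(
                ppi, degree_cutoff=config.degree_cutoff,
                node_score_cutoff=config.node_score_cutoff,
            )
            _write_tsv(netcluster.complexes_table(complexes),
                       out / "mcode_complexes.tsv", manifest)
            n_isolated = sum(1 for v in ppi.graph if ppi.graph.degree(v) == 0)
            manifest.stage_log.append(
                {"stage": "mcode", "n_nodes": len(ppi.nodes),
                 "n_edges": ppi.n_edges, "n_isolated_excluded": n_isolated,
                 "n_complexes": len(complexes)}
            )
        except Exception as exc:
            raise StageError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n"
    )
    return manifest
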