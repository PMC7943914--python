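"""End-to-end pipeline: simulate (optional) -> qc -> embed -> cnv -> diversity ->
noise -> shift -> markers -> network -> talk -> score.

The configuration is a strict (unknown keys rejected) YAML-backed model whose
stage parameters mirror the module defaults, except where the bundled ~4,500-cell
synthetic fixture warrants smaller inclusion thresholds (see the stage models).
A single global seed is expanded into per-stage streams so inserting a stage does
not shift downstream randomness; rerunning an identical config reproduces every
output bit-identically. Each stage writes flat TSV/JSON outputs plus a manifest
recording its parameters, seed, and SHA-256 hashes of its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict
from sklearn.cluster import KMeans

from . import cnv as cnv_mod
from . import heterogeneity, interactions, lineage_shift, network, signatures, simulate
from .io_qc import QcThresholds, apply_qc, normalize_log, select_hvg_and_pca
from .markers import condition_genes, domain_clusters

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_pipeline"]

STAGES = ("simulate", "qc", "embed", "cnv", "diversity", "noise", "shift",
          "markers", "network", "talk", "score")

REFERENCE_TYPES = ("T_cell", "B_cell", "myeloid", "fibroblast")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateCfg(_Strict):
    enabled: bool = True
    n_patients_per_condition: int = 3
    n_cells_per_patient: int = 500
    n_genes: int = 2000


class QcCfg(_Strict):
    min_genes: int = 200
    max_genes: int = 7000
    max_mito_fraction: float = 0.20


class EmbedCfg(_Strict):
    n_hvg: int = 2000
    n_pcs: int = 50


class CnvCfg(_Strict):
    window: int = 101
    clip: float = 3.0
    score_quantile: float = 0.95
    corr_min: float = 0.3


class DiversityCfg(_Strict):
    # inclusion threshold scaled to the bundled fixture; the library default (500)
    # is the full-cohort rule
    min_cells: int = 100
    n_pcs: int = 10


class NoiseCfg(_Strict):
    invariant_genes: int = 150
    equalize: bool = True
    min_stratum: int = 20


class ShiftCfg(_Strict):
    n_sub: int = 150
    n_boot: int = 100
    d: int = 10


class MarkersCfg(_Strict):
    fdr_max: float = 0.01
    lfc_min: float = 0.5
    domain_threshold: float = 0.60
    n_clusters: int = 10
    cluster_cell_type: str = "myeloid"


class NetworkCfg(_Strict):
    min_cells: int = 20
    lfc_min: float = 0.5
    fdr_max: float = 0.05


class TalkCfg(_Strict):
    min_cells: int = 10
    min_patient_frac: float = 0.5


class ScoreCfg(_Strict):
    n_perm: int = 1000


class RunConfig(_Strict):
    out_dir: str = "scith_run"
    fixture_dir: str | None = None  # required when simulate.enabled is False
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateCfg = SimulateCfg()
    qc: QcCfg = QcCfg()
    embed: EmbedCfg = EmbedCfg()
    cnv: CnvCfg = CnvCfg()
    diversity: DiversityCfg = DiversityCfg()
    noise: NoiseCfg = NoiseCfg()
    shift: ShiftCfg = ShiftCfg()
    markers: MarkersCfg = MarkersCfg()
    network: NetworkCfg = NetworkCfg()
    talk: TalkCfg = TalkCfg()
    score: ScoreCfg = ScoreCfg()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(payload)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stage name."""
    return int((int(seed) % (2**31)) ^ (zlib.crc32(stage.encode()) % (2**31)))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifests:
    def __init__(self, out_dir: Path, seed: int):
        self.out_dir = out_dir
        self.seed = seed
        self.stages: list[dict] = []

    def record(self, stage: str, params: dict, inputs: list, outputs: list):
        entry = {
            "stage": stage,
            "seed": stage_seed(self.seed, stage),
            "parameters": params,
            "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
            "outputs": [str(p) for p in outputs],
        }
        path = self.out_dir / f"manifest_{stage}.json"
        path.write_text(json.dumps(entry, indent=1, sort_keys=True))
        entry["manifest"] = str(path)
        self.stages.append(entry)
        log.info("stage %s complete (%d outputs)", stage, len(outputs))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the consolidated report dictionary.

    A stage failure raises with the stage name attached; outputs of completed
    stages are retained on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = _Manifests(out, config.seed)
    current = None
    try:
        # -- simulate ----------------------------------------------------------
        current = "simulate"
        if config.simulate.enabled:
            sim_cfg = simulate.default_config(
                seed=stage_seed(config.seed, "simulate"),
                n_patients_per_condition=config.simulate.n_patients_per_condition,
                n_cells_per_patient=config.simulate.n_cells_per_patient,
                n_genes=config.simulate.n_genes,
            )
            adata, gt = simulate.simulate_cohort(sim_cfg)
            fixture = out / "fixture"
            manifest = simulate.write_fixture(adata, gt, fixture)
            man.record("simulate", config.simulate.model_dump(), [],
                       list(manifest.values()))
        else:
            if not config.fixture_dir:
                raise ValueError("fixture_dir required when simulate is disabled")
            fixture = Path(config.fixture_dir)
            adata, gt = simulate.read_fixture(fixture)
            man.record("simulate", {"enabled": False, "fixture": str(fixture)},
                       [fixture / "matrix.mtx"], [])

        fixture_files = sorted(str(p) for p in Path(fixture).glob("*") if p.is_file())

        # -- qc ----------------------------------------------------------------
        current = "qc"
        thresholds = QcThresholds(config.qc.min_genes, config.qc.max_genes,
                                  config.qc.max_mito_fraction)
        adata, qc_report = apply_qc(adata, thresholds)
        qc_path = out / "qc_report.json"
        qc_path.write_text(json.dumps(qc_report, indent=1))
        man.record("qc", config.qc.model_dump(), fixture_files, [qc_path])

        # -- embed -------------------------------------------------------------
        current = "embed"
        normalize_log(adata)
        emb = select_hvg_and_pca(adata, n_hvg=config.embed.n_hvg,
                                 n_pcs=config.embed.n_pcs)
        emb_path = out / "embedding.tsv"
        emb.to_frame().rename_axis("barcode").to_csv(emb_path, sep="\t")
        man.record("embed", config.embed.model_dump(), [qc_path], [emb_path])

        # -- cnv ---------------------------------------------------------------
        current = "cnv"
        ref_cells = adata.obs_names[
            adata.obs["cell_type"].isin(REFERENCE_TYPES)].tolist()
        profile = cnv_mod.infer_cnv(adata, ref_cells, window=config.cnv.window,
                                    clip=config.cnv.clip)
        score = cnv_mod.malignancy_score(profile,
                                         score_quantile=config.cnv.score_quantile,
                                         corr_min=config.cnv.corr_min)
        cnv_path = out / "malignancy.tsv"
        pd.DataFrame({"malignancy_score": score.scores,
                      "putatively_malignant": score.flags}) \
            .rename_axis("barcode").to_csv(cnv_path, sep="\t")
        man.record("cnv", config.cnv.model_dump(), [emb_path], [cnv_path])

        # -- diversity ---------------------------------------------------------
        current = "diversity"
        div, excluded = heterogeneity.diversity_score(
            emb, adata.obs, min_cells=config.diversity.min_cells,
            n_pcs=config.diversity.n_pcs)
        cmp_res = heterogeneity.compare_diversity(div) if len(div) else {}
        div_path = out / "diversity.tsv"
        div.to_csv(div_path, sep="\t", index=False)
        div_cmp_path = out / "diversity_comparison.json"
        div_cmp_path.write_text(json.dumps(
            {"comparison": cmp_res,
             "excluded": excluded.to_dict(orient="records")}, indent=1))
        man.record("diversity", config.diversity.model_dump(), [emb_path, cnv_path],
                   [div_path, div_cmp_path])

        # -- noise -------------------------------------------------------------
        current = "noise"
        noise_table, per_type = heterogeneity.transcriptional_noise(
            adata, invariant_genes=config.noise.invariant_genes,
            equalize=config.noise.equalize, seed=stage_seed(config.seed, "noise"),
            min_stratum=config.noise.min_stratum)
        noise_path = out / "noise.tsv"
        noise_table.to_csv(noise_path, sep="\t", index=False)
        noise_type_path = out / "noise_per_type.tsv"
        per_type.to_csv(noise_type_path, sep="\t", index=False)
        man.record("noise", config.noise.model_dump(), [qc_path],
                   [noise_path, noise_type_path])

        # -- shift -------------------------------------------------------------
        current = "shift"
        immune = [t for t in sorted(adata.obs["cell_type"].unique())
                  if t not in ("cancer", "epithelial")]
        results, skipped = lineage_shift.lineage_shift_all(
            emb, adata.obs, cell_types=immune, n_sub=config.shift.n_sub,
            n_boot=config.shift.n_boot, d=config.shift.d,
            seed=stage_seed(config.seed, "shift"))
        shift_path = out / "lineage_shift.json"
        shift_path.write_text(json.dumps({
            "results": [{
                "cell_type": r.cell_type, "fold_change": r.fold_change, "p": r.p,
                "mean_observed": float(np.mean(r.observed)),
                "mean_null": float(np.mean(r.null)),
                "n_sub": r.n_sub, "d": r.d,
            } for r in results],
            "skipped": skipped}, indent=1))
        man.record("shift", config.shift.model_dump(), [emb_path], [shift_path])

        # -- markers -----------------------------------------------------------
        current = "markers"
        sets, top_table, detail = condition_genes(
            adata, fdr_max=config.markers.fdr_max, lfc_min=config.markers.lfc_min)
        sets_path = out / "condition_genes.json"
        sets_path.write_text(json.dumps(sets, indent=1))
        top_path = out / "condition_genes_top.tsv"
        top_table.to_csv(top_path, sep="\t", index=False)
        # domain clusters over the configured lineage (macrophage-style re-clustering)
        dom_path = out / "domain_clusters.tsv"
        lineage_mask = (adata.obs["cell_type"]
                        == config.markers.cluster_cell_type).to_numpy()
        if lineage_mask.sum() >= config.markers.n_clusters:
            km = KMeans(n_clusters=config.markers.n_clusters, n_init=10,
                        random_state=stage_seed(config.seed, "markers") % (2**31))
            labels = km.fit_predict(emb.coordinates[lineage_mask, :10])
            dom = domain_clusters(labels,
                                  adata.obs.loc[lineage_mask, "condition"],
                                  threshold=config.markers.domain_threshold)
            dom.assign(composition=dom["composition"].map(json.dumps)) \
                .to_csv(dom_path, sep="\t", index=False)
        else:
            pd.DataFrame().to_csv(dom_path, sep="\t")
        man.record("markers", config.markers.model_dump(), [qc_path],
                   [sets_path, top_path, dom_path])

        # -- network -----------------------------------------------------------
        current = "network"
        nets = network.build_network(adata, min_cells=config.network.min_cells)
        stage_m = network.stage_markers(adata, lfc_min=config.network.lfc_min,
                                        fdr_max=config.network.fdr_max)
        net_path = out / "network.json"
        net_path.write_text(json.dumps({
            cond: {"hub": tn.hub,
                   "nodes": tn.nodes.to_dict(orient="records"),
                   "edges": tn.edges.to_dict(orient="records"),
                   "dropped": tn.dropped}
            for cond, tn in nets.items()}, indent=1))
        stage_path = out / "stage_markers.tsv"
        pd.concat([df.assign(stage=stage) for stage, df in stage_m.items()],
                  ignore_index=True).to_csv(stage_path, sep="\t", index=False) \
            if stage_m else pd.DataFrame().to_csv(stage_path, sep="\t")
        man.record("network", config.network.model_dump(), [qc_path],
                   [net_path, stage_path])

        # -- talk --------------------------------------------------------------
        current = "talk"
        if gt is not None and gt.lr_pairs:
            pairs = pd.DataFrame(gt.lr_pairs)[["ligand", "receptor"]]
        else:
            pairs = interactions.load_lr_pairs(
                Path(__file__).parent / "data" / "lr_pairs.csv")
        table = interactions.call_interactions(
            adata, pairs, min_cells=config.talk.min_cells,
            min_patient_frac=config.talk.min_patient_frac)
        talk_path = out / "interactions.tsv"
        table.to_csv(talk_path, sep="\t", index=False)
        talk_sum_path = out / "interactions_summary.tsv"
        interactions.summarize_interactions(table).to_csv(
            talk_sum_path, sep="\t", index=False)
        man.record("talk", config.talk.model_dump(), [qc_path],
                   [talk_path, talk_sum_path])

        # -- score -------------------------------------------------------------
        current = "score"
        if gt is not None and gt.type_program:
            panels = [signatures.GenePanel(f"{t}_program", tuple(v["genes"]))
                      for t, v in sorted(gt.type_program.items())]
            gene_sets = {p.name: list(p.genes) for p in panels}
        else:
            panels = signatures.load_panels(
                Path(__file__).parent / "data" / "panels.tsv")
            gene_sets = {p.name: list(p.genes) for p in panels}
        pscores = signatures.panel_scores(adata, panels)
        score_path = out / "panel_scores.tsv"
        pscores.rename_axis("barcode").to_csv(score_path, sep="\t")
        act = signatures.pathway_activity(
            adata, gene_sets, n_perm=config.score.n_perm,
            seed=stage_seed(config.seed, "score"))
        act_path = out / "pathway_activity.tsv"
        act.to_csv(act_path, sep="\t", index=False)
        man.record("score", config.score.model_dump(), [qc_path],
                   [score_path, act_path])
    except Exception as exc:  # noqa: BLE001 - annotate failures with the stage
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    report = {
        "seed": config.seed,
        "out_dir": str(out),
        "stages": [{k: v for k, v in s.items() if k != "inputs"}
                   for s in man.stages],
        "n_stages": len(man.stages),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
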