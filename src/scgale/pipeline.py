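"""End-to-end orchestration: preprocess → geometry → autoencoder → graph →
classifier → explainer → metrics, plus the ablation harness.

Every stage writes its outputs under the configured directory and is listed
in a run manifest (config snapshot, per-stage wall time, output paths,
seeds). A stage failure aborts with the stage name and a partial manifest.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as sio
from .autoencoder import (TrainConfig, TrainedAutoencoder, corrupt_dropout,
                          pca_embed, reconstruct, train_ae, train_grae,
                          train_vae)
from .classifier import GATConfig, train_classifier
from .containers import CountMatrix
from .explain import ExplainerConfig, explain_class
from .geometry import GeometryParams, phate_embed
from .graph import knn_graph
from .metrics import (estimate_nb_dispersion, homogeneity, mse,
                      mse_top_covered, nb_loss, spearman, specificity,
                      stability, xai_da_similarity)
from .preprocess import (log_transform, normalize_library_size, qc_filter_gex,
                         qc_filter_peaks, select_hv_peaks, select_hvg_gex,
                         wilcoxon_da)

__all__ = ["PipelineConfig", "RunManifest", "StageError", "run_all",
           "run_stages", "run_ablation", "embed_with"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: "RunManifest"):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.manifest = manifest


@dataclass
class PipelineConfig:
    input: Optional[str] = None
    input_format: str = "h5ad"  # h5ad | mtx | dense
    modality: str = "GEX"
    outdir: str = "scgale_run"
    do_qc: bool = True
    target_sum: str | float = "median"
    feature_selection: str = "none"  # auto | hvg | hv_peaks | none
    n_top: int = 50
    k: int = 15
    seed: int = 0
    arch: str = "GAT"
    explain_subsample: Optional[int] = 100
    train: TrainConfig = field(default_factory=TrainConfig)
    gat: GATConfig = field(default_factory=GATConfig)
    explainer: ExplainerConfig = field(default_factory=ExplainerConfig)
    geometry: GeometryParams = field(default_factory=GeometryParams)

    def __post_init__(self):
        # one global seed propagates to every stage unless overridden
        self.train = replace(self.train, seed=self.train.seed or self.seed)
        self.gat = replace(self.gat, seed=self.gat.seed or self.seed)
        self.explainer = replace(self.explainer,
                                 seed=self.explainer.seed or self.seed)
        self.geometry = replace(self.geometry,
                                seed=self.geometry.seed or self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("train", TrainConfig), ("gat", GATConfig),
                         ("explainer", ExplainerConfig),
                         ("geometry", GeometryParams)):
            if key in d and isinstance(d[key], dict):
                sd = dict(d[key])
                if key == "gat" and isinstance(sd.get("split"), list):
                    sd["split"] = tuple(sd["split"])
                d[key] = sub(**sd)
        return cls(**d)

    def save_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunManifest:
    config: dict
    version: str = "0.1.0"
    stages: List[dict] = field(default_factory=list)
    outputs: Dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, seconds: float, outputs: Dict[str, str]):
        self.stages.append({"stage": stage, "wall_time_s": round(seconds, 3)})
        self.outputs.update(outputs)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "version": self.version,
                       "stages": self.stages, "outputs": self.outputs}, fh,
                      indent=2, default=str)


def _load_input(cfg: PipelineConfig) -> CountMatrix:
    if cfg.input is None:
        raise ValueError("pipeline config has no input path")
    if cfg.input_format == "h5ad":
        return sio.read_h5ad(cfg.input, modality=cfg.modality)
    if cfg.input_format == "mtx":
        return sio.read_mtx_dir(cfg.input, modality=cfg.modality)
    if cfg.input_format == "dense":
        sep = "," if cfg.input.endswith(".csv") else "\t"
        return sio.read_dense(cfg.input, sep=sep, modality=cfg.modality)
    raise ValueError(f"unknown input_format {cfg.input_format!r}")


def embed_with(kind: str, m: CountMatrix, cfg: PipelineConfig,
               xi=None) -> TrainedAutoencoder:
    """Train one of the embedding methods on a processed matrix."""
    if kind == "GRAE":
        if xi is None:
            xi = phate_embed(m, params=cfg.geometry)
        return train_grae(m, xi, cfg.train)
    if kind == "AE":
        return train_ae(m, cfg.train)
    if kind == "VAE":
        return train_vae(m, cfg.train)
    if kind == "PCA":
        return pca_embed(m)
    raise ValueError(f"unknown embedder {kind!r}")


def run_stages(m: CountMatrix, cfg: PipelineConfig) -> RunManifest:
    """Run the full pipeline on an in-memory matrix; see :func:`run_all`."""
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict())

    def _stage(name):
        class _Ctx:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                self_.outputs = {}
                return self_

            def __exit__(self_, exc_type, exc, tb):
                if exc is not None:
                    manifest.save(os.path.join(cfg.outdir, "manifest.partial.json"))
                    raise StageError(name, exc, manifest) from exc
                manifest.record(name, time.perf_counter() - self_.t0,
                                self_.outputs)
        return _Ctx()

    # ---- stage I: preprocessing -----------------------------------------
    with _stage("preprocess") as st:
        proc = m
        if cfg.do_qc:
            if m.modality == "GEX":
                proc, qc_report = qc_filter_gex(proc)
            else:
                proc, qc_report = qc_filter_peaks(proc)
            qc_path = os.path.join(cfg.outdir, "qc_report.json")
            qc_report.to_json(qc_path)
            st.outputs["qc_report"] = qc_path
        proc = normalize_library_size(proc, cfg.target_sum)
        sel = cfg.feature_selection
        if sel == "auto":
            sel = "hvg" if proc.modality == "GEX" else "hv_peaks"
        if sel == "hvg":
            proc = select_hvg_gex(proc)
        elif sel == "hv_peaks":
            proc = select_hv_peaks(proc)
        elif sel != "none":
            raise ValueError(f"unknown feature_selection {cfg.feature_selection!r}")
        proc = log_transform(proc)
        proc_path = os.path.join(cfg.outdir, "processed")
        sio.write_mtx_dir(proc, proc_path)
        st.outputs["processed_matrix"] = proc_path

    # ---- stage II: geometry + embedding + graph -------------------------
    with _stage("geometry") as st:
        xi = phate_embed(proc, params=cfg.geometry)
        path = os.path.join(cfg.outdir, "geometry_coords.tsv")
        sio.write_coords_tsv(proc.cell_ids, xi.coords, path)
        st.outputs["geometry_coords"] = path

    with _stage("embedding") as st:
        model = train_grae(proc, xi, cfg.train)
        path = os.path.join(cfg.outdir, "latent.tsv")
        sio.write_coords_tsv(proc.cell_ids, model.latent, path, prefix="z")
        st.outputs["latent"] = path

    with _stage("graph") as st:
        graph = knn_graph(model.latent, k=cfg.k, source="GRAE")
        path = os.path.join(cfg.outdir, "edges.tsv")
        sio.write_edge_list(graph, path)
        st.outputs["edges"] = path

    # ---- stage III: classification --------------------------------------
    with _stage("classifier") as st:
        if proc.labels is None:
            raise ValueError("cell labels are required to train the classifier")
        clf, report = train_classifier(graph, proc, cfg.gat, arch=cfg.arch)
        path = os.path.join(cfg.outdir, "classification_report.json")
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        st.outputs["classification_report"] = path
        pred = clf.predict(X=proc.counts)
        proba = clf.predict_proba(X=proc.counts)
        pred_path = os.path.join(cfg.outdir, "predictions.tsv")
        pd.DataFrame({
            "cell_id": proc.cell_ids.astype(str),
            "predicted": pred,
            "probability": proba.max(axis=1),
        }).to_csv(pred_path, sep="\t", index=False)
        st.outputs["predictions"] = pred_path

    # ---- stage IV: explanation + metrics --------------------------------
    with _stage("explainer") as st:
        explanations = explain_class(
            clf, graph, proc.counts, proc.labels, cfg.explainer,
            n_top=cfg.n_top, feature_ids=proc.feature_ids,
            subsample_cap=cfg.explain_subsample,
        )
        for cls, exp in explanations.items():
            path = os.path.join(cfg.outdir, f"explanation_{cls}.tsv")
            pd.DataFrame({
                "rank": np.arange(1, cfg.n_top + 1),
                "feature_id": exp.top_set(cfg.n_top),
                "importance": exp.ranked_importance[:cfg.n_top],
            }).to_csv(path, sep="\t", index=False)
            st.outputs[f"explanation_{cls}"] = path

    with _stage("metrics") as st:
        top_sets = {c: e.top_set(cfg.n_top) for c, e in explanations.items()}
        da = wilcoxon_da(proc, n_top=cfg.n_top)
        da_sets = da.top_sets()
        sim = {
            c: xai_da_similarity(top_sets[c], da_sets[c], n=cfg.n_top)
            for c in top_sets
        }
        results = {
            "homogeneity": homogeneity(graph, proc.labels),
            "specificity": specificity(top_sets, n=cfg.n_top),
            "xai_da_similarity": sim,
            "classification": report.to_dict(),
        }
        path = os.path.join(cfg.outdir, "metrics.json")
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2)
        st.outputs["metrics"] = path

    manifest.save(os.path.join(cfg.outdir, "manifest.json"))
    return manifest


def run_all(cfg: PipelineConfig) -> RunManifest:
    """Load the configured input and run all pipeline stages."""
    return run_stages(_load_input(cfg), cfg)


def run_ablation(
    m: CountMatrix,
    cfg: PipelineConfig,
    embedders=("GRAE", "AE", "VAE", "PCA"),
    arches=("GAT",),
    dropout_levels=(0.1, 0.2, 0.3, 0.4, 0.5),
    n_repeats: int = 5,
    include_classification: bool = False,
) -> pd.DataFrame:
    """Corruption-recovery and latent-quality ablation on a processed matrix.

    For every embedder × dropout level × repeat, the matrix is corrupted
    (whole feature columns zeroed), the embedder retrained on the corrupted
    matrix, and the reconstruction scored against the original (MSE,
    MSE1obs, MSE1imp, NB loss, Spearman). Per embedder, the uncorrupted
    latent k-NN graph homogeneity is reported; optionally, classification
    metrics and explanation specificity/stability over repeats. Returns a
    long-format table (embedder, arch, dropout, repeat, metric, value).
    """
    if not embedders:
        raise ValueError("embedders must be non-empty")
    rows = []
    X = m.counts
    theta = estimate_nb_dispersion(np.expm1(X) if m.is_log else X)

    for kind in embedders:
        for level in dropout_levels:
            for rep in range(n_repeats):
                seed = cfg.seed + 1000 * rep + int(level * 10)
                corrupted, _ = corrupt_dropout(m, level, seed=seed)
                tcfg = replace(cfg.train, seed=seed)
                rcfg = replace(cfg, train=tcfg,
                               geometry=replace(cfg.geometry, seed=seed))
                model = embed_with(kind, corrupted, rcfg)
                xhat = reconstruct(model, corrupted)
                scores = {
                    "mse": mse(X, xhat),
                    "mse1obs": mse_top_covered(X, xhat, basis="observed"),
                    "mse1imp": mse_top_covered(X, xhat, basis="imputed"),
                    "nb_loss": nb_loss(np.expm1(X) if m.is_log else X,
                                       np.expm1(np.maximum(xhat, 0.0))
                                       if m.is_log else np.maximum(xhat, 0.0),
                                       theta),
                    "spearman": spearman(X, xhat),
                }
                for metric, value in scores.items():
                    rows.append({"embedder": kind, "arch": "", "dropout": level,
                                 "repeat": rep, "metric": metric,
                                 "value": value})

        # latent quality without corruption
        if m.labels is not None:
            model = embed_with(kind, m, cfg)
            g = knn_graph(model.latent, k=cfg.k, source=kind)
            rows.append({"embedder": kind, "arch": "", "dropout": 0.0,
                         "repeat": 0, "metric": "homogeneity",
                         "value": homogeneity(g, m.labels)})
            if include_classification:
                for arch in arches:
                    run_sets = []
                    for rep in range(max(2, n_repeats)):
                        gcfg = replace(cfg.gat, seed=cfg.seed + rep)
                        clf, report = train_classifier(g, m, gcfg, arch=arch)
                        for metric in ("accuracy", "precision", "recall", "f1"):
                            rows.append({
                                "embedder": kind, "arch": arch, "dropout": 0.0,
                                "repeat": rep, "metric": metric,
                                "value": getattr(report, metric),
                            })
                        ecfg = replace(cfg.explainer, seed=cfg.seed + rep)
                        exp = explain_class(
                            clf, g, m.counts, m.labels, ecfg, n_top=cfg.n_top,
                            feature_ids=m.feature_ids,
                            subsample_cap=cfg.explain_subsample,
                        )
                        run_sets.append(
                            {c: e.top_set(cfg.n_top) for c, e in exp.items()}
                        )
                    rows.append({"embedder": kind, "arch": arch, "dropout": 0.0,
                                 "repeat": -1, "metric": "specificity",
                                 "value": specificity(run_sets[0], n=cfg.n_top)})
                    rows.append({"embedder": kind, "arch": arch, "dropout": 0.0,
                                 "repeat": -1, "metric": "stability",
                                 "value": stability(run_sets, n=cfg.n_top)})
    return pd.DataFrame(rows)


def aggregate_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and 3 × standard-error bars per embedder × dropout × metric."""
    def _agg(g):
        n = len(g)
        sem = g["value"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        return pd.Series({"mean": g["value"].mean(), "uncertainty": 3 * sem,
                          "n": n})

    return (table.groupby(["embedder", "arch", "dropout", "metric"])
            .apply(_agg, include_groups=False).reset_index())
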