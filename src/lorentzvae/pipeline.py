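"""End-to-end orchestration: preprocess -> fit -> embed -> evaluate.

A run resolves a :class:`RunConfig` into a self-describing output directory
containing the checkpoint, latent CSV, loss-trace CSV, metric report JSON,
effective config YAML and a log file. ``run_sweep`` repeats a run along one
configuration axis (geometric weight, bottleneck/latent dimension,
likelihood family, pathway ablation, or geometric-loss anchoring) and
tabulates metric deltas against the first value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .metrics import MetricReport, evaluate
from .model import LorentzVAE, ModelConfig
from .preprocessing import ProcessedDataset, preprocess

logger = logging.getLogger("lorentzvae")

SWEEP_AXES = {
    "lambda_geo": "lambda_geo",
    "bottleneck_dim": "bottleneck_dim",
    "latent_dim": "latent_dim",
    "likelihood": "likelihood",
    "ablation": None,       # values: full / no_main / no_bn
    "geo_anchor": "geo_anchor",
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML."""

    input_path: str
    modality: str = "rna"
    labels_path: Optional[str] = None
    batch_path: Optional[str] = None
    out_dir: str = "runs/run"
    n_top_features: Optional[int] = None
    model: ModelConfig = field(default_factory=ModelConfig)
    umap_metrics: bool = True
    tsne_metrics: bool = True
    embed_mode: str = "mean"
    seed: int = 0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        model = ModelConfig(**d.pop("model", {}))
        return cls(model=model, **d)


def _load_inputs(cfg: RunConfig):
    X = lio.read_counts(cfg.input_path, cfg.modality)
    labels = lio.read_label_csv(cfg.labels_path) if cfg.labels_path else None
    batch = lio.read_label_csv(cfg.batch_path) if cfg.batch_path else None
    return X, labels, batch


def run_pipeline(cfg: RunConfig, *, data: Optional[ProcessedDataset] = None,
                 labels=None, batch=None) -> Path:
    """Execute one run; returns the output directory.

    Inputs may be passed in-memory (``data``/``labels``/``batch``) or read
    from the paths in the config. The model seed is taken from the run seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        mcfg = replace(cfg.model, seed=cfg.seed)
        cfg = replace(cfg, model=mcfg)
        (out / "config.yaml").write_text(cfg.to_yaml())
        if data is None:
            X, labels, batch = _load_inputs(cfg)
            logger.info("loaded %d cells x %d features (%s)",
                        X.n_cells, X.n_features, cfg.modality)
            data = preprocess(X, n_top=cfg.n_top_features)
        logger.info("selected %d features; fitting (likelihood=%s, "
                    "lambda_geo=%.3g)", data.n_features, mcfg.likelihood,
                    mcfg.lambda_geo)
        model = LorentzVAE(data.n_features, mcfg)
        trace = model.fit(data)
        trace.to_csv(out / "loss_trace.csv", index=False)
        for _, row in trace.iloc[[0, len(trace) - 1]].iterrows():
            logger.info("epoch %d: total=%.4f recon1=%.4f recon2=%.4f "
                        "kl=%.4f geo=%.4f", int(row.epoch), row.total,
                        row.recon1, row.recon2, row.kl, row.geo)
        model.save(out / "checkpoint.npz")
        Z = model.embed(data, mode=cfg.embed_mode, seed=cfg.seed)
        lio.write_latent_csv(Z, data.cell_ids, out / "latent.csv")
        report = evaluate(Z, labels=labels, batch=batch,
                          umap_metrics=cfg.umap_metrics,
                          tsne_metrics=cfg.tsne_metrics, seed=cfg.seed)
        report.to_json(out / "metrics.json")
        logger.info("run complete: %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def evaluate_run(out_dir, *, data: Optional[ProcessedDataset] = None,
                 labels=None, batch=None) -> MetricReport:
    """Recompute the MetricReport from a stored checkpoint + config."""
    out = Path(out_dir)
    cfg = RunConfig.from_yaml((out / "config.yaml").read_text())
    model = LorentzVAE.load(out / "checkpoint.npz")
    if data is None:
        X, labels, batch = _load_inputs(cfg)
        data = preprocess(X, n_top=cfg.n_top_features)
    Z = model.embed(data, mode=cfg.embed_mode, seed=cfg.seed)
    return evaluate(Z, labels=labels, batch=batch,
                    umap_metrics=cfg.umap_metrics,
                    tsne_metrics=cfg.tsne_metrics, seed=cfg.seed)


def _apply_axis(mcfg: ModelConfig, axis: str, value) -> ModelConfig:
    if axis == "ablation":
        if value == "full":
            return replace(mcfg, use_main_path=True, use_bn_path=True)
        if value == "no_main":
            return replace(mcfg, use_main_path=False, use_bn_path=True)
        if value == "no_bn":
            return replace(mcfg, use_main_path=True, use_bn_path=False,
                           lambda_geo=0.0)
        raise ValueError(f"ablation value must be full/no_main/no_bn, got {value!r}")
    field_name = SWEEP_AXES[axis]
    return replace(mcfg, **{field_name: value})


def run_sweep(cfg: RunConfig, axis: str, values: Sequence, *,
              data: Optional[ProcessedDataset] = None, labels=None,
              batch=None) -> pd.DataFrame:
    """One sub-run per axis value (shared seed); returns the aggregated
    metric table with deltas relative to the first value."""
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; choose from {sorted(SWEEP_AXES)}")
    # validate every value before any run starts
    for v in values:
        _apply_axis(cfg.model, axis, v)
    rows = []
    base = Path(cfg.out_dir)
    for v in values:
        sub = replace(cfg, model=_apply_axis(cfg.model, axis, v),
                      out_dir=str(base / f"{axis}_{v}"))
        out = run_pipeline(sub, data=data, labels=labels, batch=batch)
        scores = json.loads((out / "metrics.json").read_text())
        rows.append({"axis": axis, "value": v, **scores})
    table = pd.DataFrame(rows)
    metric_cols = [c for c in table.columns if c not in ("axis", "value")]
    deltas = table[metric_cols] - table[metric_cols].iloc[0]
    deltas.columns = [f"delta_{c}" for c in metric_cols]
    table = pd.concat([table, deltas], axis=1)
    table.to_csv(base / f"sweep_{axis}.csv", index=False)
    return table
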