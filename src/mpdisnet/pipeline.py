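"""End-to-end orchestration: integrate -> walk -> train -> score/evaluate.

One YAML config describes the layer files, the meta-paths with their walk
and training parameters, the fusion order and an optional label file.  A
single global seed deterministically derives one seed per stage (global
seed + stage index, in execution order), so a rerun with the same config
and seed reproduces every output byte for byte.  Each output is written
through a temp file that is renamed on success; a failed stage leaves a
``.partial`` file behind and aborts with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .evaluation import evaluate, read_labels
from .graph_io import read_network
from .similarity import (
    concatenate_embeddings,
    cosine_table,
    write_similarity_table,
)
from .skipgram import EmbeddingMatrix, SkipgramConfig, train
from .walker import WalkConfig, generate_corpus, get_metapath, write_corpus

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class MetaPathStage:
    """Walk + training parameters for one meta-path."""

    name: str
    steps_per_walk: int = 50
    walks_per_node: int = 1000
    dimension: int = 128
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    noise_exponent: float = 0.75


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    layers: dict[str, Path]
    metapaths: list[MetaPathStage]
    outdir: Path
    seed: int = 0
    labels: Path | None = None
    fusion_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.metapaths]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate meta-path names in config: {names}")
        if not self.metapaths:
            raise ValueError("config lists no meta-paths")
        if not self.fusion_order:
            self.fusion_order = names
        if set(self.fusion_order) != set(names):
            raise ValueError("fusion_order must permute the configured meta-paths")
        for layer, path in self.layers.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"layer {layer!r}: no such file {path}")
        if self.labels is not None and not Path(self.labels).exists():
            raise FileNotFoundError(f"label file not found: {self.labels}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        base = Path(path).parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        stages = []
        for m in raw.get("metapaths", []):
            if isinstance(m, str):
                stages.append(MetaPathStage(name=m))
            else:
                stages.append(MetaPathStage(**m))
        return cls(
            layers={k: resolve(v) for k, v in raw.get("layers", {}).items()},
            metapaths=stages,
            outdir=resolve(raw.get("outdir", "mpdisnet_out")),
            seed=int(raw.get("seed", 0)),
            labels=resolve(raw["labels"]) if raw.get("labels") else None,
            fusion_order=list(raw.get("fusion_order", [])),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _commit(tmp: Path, final: Path) -> None:
    tmp.replace(final)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the four-step pipeline; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "mpdisnet",
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    stage_index = 0

    def run_stage(name: str, fn):
        nonlocal stage_index
        stage_seed = config.seed + stage_index
        logger.info("stage %d (%s), seed %d", stage_index, name, stage_seed)
        try:
            result = fn(stage_seed)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"index": stage_index, "name": name, "seed": stage_seed})
        stage_index += 1
        return result

    network = run_stage("integrate", lambda _s: read_network(config.layers))
    manifest["network"] = {
        "n_nodes": network.n_nodes,
        "layer_edge_counts": network.layer_edge_counts,
    }

    embeddings: dict[str, EmbeddingMatrix] = {}
    for stage in config.metapaths:

        def do_walk(s, stage=stage):
            corpus = generate_corpus(
                network,
                get_metapath(stage.name),
                WalkConfig(
                    steps_per_walk=stage.steps_per_walk,
                    walks_per_node=stage.walks_per_node,
                    seed=s,
                ),
            )
            tmp = outdir / f"corpus_{stage.name}.txt.partial"
            write_corpus(corpus, tmp, seed=s)
            _commit(tmp, outdir / f"corpus_{stage.name}.txt")
            return corpus

        corpus = run_stage(f"walk[{stage.name}]", do_walk)

        def do_train(s, stage=stage, corpus=corpus):
            emb = train(
                corpus,
                SkipgramConfig(
                    dimension=stage.dimension,
                    window=stage.window,
                    negatives=stage.negatives,
                    epochs=stage.epochs,
                    learning_rate=stage.learning_rate,
                    noise_exponent=stage.noise_exponent,
                    seed=s,
                ),
            )
            tmp = outdir / f"emb_{stage.name}.tsv.partial"
            emb.to_tsv(tmp)
            _commit(tmp, outdir / f"emb_{stage.name}.tsv")
            return emb

        embeddings[stage.name] = run_stage(f"train[{stage.name}]", do_train)

    def do_score(_s):
        ordered = [embeddings[name] for name in config.fusion_order]
        fused = concatenate_embeddings(ordered)
        table = cosine_table(
            fused, metapaths="+".join(config.fusion_order)
        )
        table = table.sort_values(["disease_a", "disease_b"]).reset_index(drop=True)
        tmp = outdir / "sims.tsv.partial"
        write_similarity_table(table, tmp)
        _commit(tmp, outdir / "sims.tsv")
        return fused, table

    fused, sims = run_stage("score", do_score)
    manifest["embedding_dimension"] = fused.dimension

    if config.labels is not None:

        def do_eval(_s):
            labels = read_labels(config.labels)
            result = evaluate(sims, labels)
            tmp = outdir / "metrics.json.partial"
            result.to_json(tmp, extra={"seed": config.seed})
            _commit(tmp, outdir / "metrics.json")
            return result

        run_stage("evaluate", do_eval)

    for name in ("sims.tsv", "metrics.json", *(f"emb_{m.name}.tsv" for m in config.metapaths)):
        p = outdir / name
        if p.exists():
            manifest["outputs"][name] = _sha256(p)

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
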