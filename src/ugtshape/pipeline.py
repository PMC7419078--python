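"""End-to-end orchestration: simulate → featurize → train → embed → analyze.

A single YAML config drives the run. Every stage persists its artifact in an
open format (TSV, npz) under the output directory, records SHA-256 digests
in a manifest, and is skipped on re-runs when its inputs and outputs are
unchanged. One global seed deterministically derives the per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .contacts import (
    ResidueSelection,
    build_dataset,
    load_dataset,
    parse_selection,
    save_dataset,
)
from .cvae import (
    CvaeConfig,
    TrainedCVAE,
    encode,
    export_embedding_tsv,
    load_embedding_tsv,
    train,
)
from .errors import ConfigError
from .latent import (
    export_report_tsv,
    plot_embedding,
    project_2d,
    representative_frames,
    separability,
)
from .structure_io import read_ensemble_pdb, read_ensemble_tsv, write_ensemble_tsv
from .synthetic import shared_state_ensembles, substrate_specific_ensembles

log = logging.getLogger("ugtshape.pipeline")

_TOP_KEYS = {"seed", "outdir", "log_level", "simulate", "ensembles",
             "contact", "cvae", "tsne", "analysis"}
_DEFAULTS = {
    "contact": {"cutoff": 8.0, "split_ratio": 0.8},
    "cvae": {"latent_dim": 3, "filters": [16, 16, 16], "learning_rate": 0.001,
             "batch_size": 64, "max_epochs": 200, "patience": 10,
             "convergence_tol": 1e-3},
    "tsne": {"perplexity": 30.0, "n_iter": 1000},
    "analysis": {"group_by": "substrate", "threshold": 0.25},
    "simulate": {"scenario": "substrate-specific", "substrates": ["UDP-Glc", "UDP-Gal"],
                 "n_frames": 1000, "n_residues": 21, "noise_sigma": 1.0},
}


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    contact: dict
    cvae: dict
    tsne: dict
    analysis: dict
    simulate: dict | None = None
    ensembles: list[dict] = field(default_factory=list)
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        offsets = {"simulate": 0, "featurize": 1, "train": 2, "embed": 3, "analyze": 4}
        return (self.seed + 7919 * offsets[stage]) % (2**31 - 1)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "version": self.version, "stages": self.stages,
             "started": self.started, "finished": self.finished},
            indent=2, default=str))


def _merge_defaults(block: dict | None, defaults: dict, applied: list[str],
                    name: str) -> dict:
    merged = dict(defaults)
    block = block or {}
    merged.update(block)
    for key, value in defaults.items():
        if key not in block:
            applied.append(f"{name}.{key} = {value}")
    return merged


def validate_config(path: str | Path) -> RunConfig:
    """Parse + validate a YAML run config, applying and logging defaults.

    All problems are aggregated into one :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    errors: list[str] = []
    applied: list[str] = []

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")
    if "seed" not in raw:
        errors.append("missing required key 'seed' (every run must be seeded)")
    if "outdir" not in raw:
        errors.append("missing required key 'outdir'")

    contact = _merge_defaults(raw.get("contact"), _DEFAULTS["contact"], applied, "contact")
    if contact["cutoff"] <= 0:
        errors.append(f"contact.cutoff must be > 0, got {contact['cutoff']}")
    if not 0 < contact["split_ratio"] < 1:
        errors.append(f"contact.split_ratio must be in (0, 1), got {contact['split_ratio']}")

    cvae_block = _merge_defaults(raw.get("cvae"), _DEFAULTS["cvae"], applied, "cvae")
    if cvae_block["learning_rate"] <= 0:
        errors.append("cvae.learning_rate must be > 0")
    tsne = _merge_defaults(raw.get("tsne"), _DEFAULTS["tsne"], applied, "tsne")
    if tsne["perplexity"] <= 0:
        errors.append("tsne.perplexity must be > 0")
    analysis = _merge_defaults(raw.get("analysis"), _DEFAULTS["analysis"], applied, "analysis")

    simulate = None
    ensembles = raw.get("ensembles") or []
    if raw.get("simulate") is not None:
        simulate = _merge_defaults(raw["simulate"], _DEFAULTS["simulate"], applied, "simulate")
        if simulate["scenario"] not in ("shared-state", "substrate-specific"):
            errors.append(f"simulate.scenario must be 'shared-state' or "
                          f"'substrate-specific', got '{simulate['scenario']}'")
    if simulate is None and not ensembles:
        errors.append("config must provide either a 'simulate' block or 'ensembles'")

    seen_labels: set[tuple[str, str]] = set()
    for k, spec in enumerate(ensembles):
        for req in ("variant", "substrate", "path"):
            if req not in spec:
                errors.append(f"ensembles[{k}]: missing '{req}'")
        if "path" in spec and not Path(spec["path"]).exists():
            errors.append(f"ensembles[{k}]: file not found: {spec['path']}")
        label = (spec.get("variant", ""), spec.get("substrate", ""))
        if label in seen_labels:
            errors.append(f"ensembles[{k}]: duplicate (variant, substrate) label {label}")
        seen_labels.add(label)
        if "selection" in spec:
            try:
                parse_selection(str(spec["selection"]))
            except Exception as exc:
                errors.append(f"ensembles[{k}]: bad selection: {exc}")

    if errors:
        raise ConfigError(f"{path}: " + "; ".join(errors))
    for line in applied:
        log.info("default applied: %s", line)
    return RunConfig(
        seed=int(raw["seed"]),
        outdir=Path(raw["outdir"]),
        contact=contact,
        cvae=cvae_block,
        tsne=tsne,
        analysis=analysis,
        simulate=simulate,
        ensembles=ensembles,
        log_level=str(raw.get("log_level", "INFO")),
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _StageRunner:
    """Runs stages with digest-based skipping of already-complete work."""

    def __init__(self, outdir: Path, manifest: RunManifest):
        self.outdir = outdir
        self.manifest = manifest
        self.state_path = outdir / ".stages.json"
        self.state = (
            json.loads(self.state_path.read_text()) if self.state_path.exists() else {}
        )

    def run(self, name: str, input_key: str, outputs: list[Path], fn) -> bool:
        """Returns True when the stage was skipped (cache hit)."""
        record = self.state.get(name)
        if (record and record["input"] == input_key
                and all(p.exists() and _digest(p) == d
                        for p, d in zip(outputs, record["outputs"]))):
            log.info("stage %s: cache hit, skipped", name)
            self.manifest.stages[name] = {**record, "skipped": True}
            return True
        log.info("stage %s: running", name)
        fn()
        digests = [_digest(p) for p in outputs]
        record = {"input": input_key, "outputs": digests,
                  "output_files": [str(p) for p in outputs], "skipped": False}
        self.state[name] = {k: record[k] for k in ("input", "outputs", "output_files")}
        self.state_path.write_text(json.dumps(self.state, indent=2))
        self.manifest.stages[name] = record
        return False


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, persisting intermediates and a manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: v for k, v in asdict(config).items()},
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    runner = _StageRunner(outdir, manifest)
    stage = "validate"
    try:
        # --- simulate ------------------------------------------------------
        ensemble_files: list[tuple[Path, str, str, str | None]] = []
        if config.simulate is not None:
            stage = "simulate"
            sim = config.simulate
            paths = [
                outdir / f"ensemble_{s.replace('/', '_')}.tsv" for s in sim["substrates"]
            ]

            def _simulate():
                builder = (shared_state_ensembles if sim["scenario"] == "shared-state"
                           else substrate_specific_ensembles)
                built = builder(
                    substrates=sim["substrates"],
                    n_frames=int(sim["n_frames"]),
                    n_residues=int(sim["n_residues"]),
                    noise_sigma=float(sim["noise_sigma"]),
                    seed=config.stage_seed("simulate"),
                )
                for ens, p in zip(built, paths):
                    write_ensemble_tsv(ens, p)

            runner.run("simulate", _digest_obj([sim, config.stage_seed("simulate")]),
                       paths, _simulate)
            for substrate, p in zip(sim["substrates"], paths):
                ensemble_files.append((p, sim["scenario"], substrate, None))
        for spec in config.ensembles:
            ensemble_files.append(
                (Path(spec["path"]), spec["variant"], spec["substrate"],
                 spec.get("selection"))
            )

        # --- featurize -----------------------------------------------------
        stage = "featurize"
        dataset_path = outdir / "dataset.npz"
        feat_key = _digest_obj([
            [(str(p), _digest(p), v, s, sel) for p, v, s, sel in ensemble_files],
            config.contact, config.stage_seed("featurize"),
        ])

        def _featurize():
            pairs = []
            for p, variant, substrate, sel_text in ensemble_files:
                reader = read_ensemble_pdb if p.suffix == ".pdb" else read_ensemble_tsv
                ens = reader(p, variant, substrate)
                sel = (parse_selection(sel_text) if sel_text
                       else ResidueSelection(tuple(int(r) for r in ens.residue_ids)))
                pairs.append((ens, sel))
            dataset = build_dataset(
                pairs,
                cutoff=float(config.contact["cutoff"]),
                split_ratio=float(config.contact["split_ratio"]),
                seed=config.stage_seed("featurize"),
            )
            save_dataset(dataset, dataset_path)

        runner.run("featurize", feat_key, [dataset_path], _featurize)

        # --- train ---------------------------------------------------------
        stage = "train"
        model_path = outdir / "cvae.npz"
        dataset = load_dataset(dataset_path)
        cvae_cfg = CvaeConfig(
            input_size=dataset.size,
            filters=tuple(config.cvae["filters"]),
            latent_dim=int(config.cvae["latent_dim"]),
            learning_rate=float(config.cvae["learning_rate"]),
            batch_size=int(config.cvae["batch_size"]),
            max_epochs=int(config.cvae["max_epochs"]),
            patience=int(config.cvae["patience"]),
            convergence_tol=float(config.cvae["convergence_tol"]),
            seed=config.stage_seed("train"),
        )
        train_key = _digest_obj([_digest(dataset_path), asdict(cvae_cfg)])
        runner.run("train", train_key, [model_path],
                   lambda: train(dataset, cvae_cfg).save(model_path))

        # --- embed ---------------------------------------------------------
        stage = "embed"
        embedding_path = outdir / "embedding.tsv"
        embed_key = _digest_obj([_digest(dataset_path), _digest(model_path)])

        def _embed():
            model = TrainedCVAE.load(model_path)
            export_embedding_tsv(encode(model, dataset), embedding_path)

        runner.run("embed", embed_key, [embedding_path], _embed)

        # --- analyze -------------------------------------------------------
        stage = "analyze"
        report_path = outdir / "separability.tsv"
        tsne_path = outdir / "tsne.tsv"
        plot_path = outdir / "tsne.png"
        reps_path = outdir / "representatives.json"
        analyze_key = _digest_obj([_digest(embedding_path), config.tsne,
                                   config.analysis, config.stage_seed("analyze")])

        def _analyze():
            embedding = load_embedding_tsv(embedding_path)
            report = separability(
                embedding,
                group_by=config.analysis["group_by"],
                threshold=float(config.analysis["threshold"]),
            )
            export_report_tsv(report, report_path)
            emb2d = project_2d(
                embedding,
                perplexity=float(config.tsne["perplexity"]),
                seed=config.stage_seed("analyze"),
                n_iter=int(config.tsne["n_iter"]),
            )
            import pandas as pd

            frame = pd.DataFrame(emb2d.labels, columns=["variant", "substrate", "frame"])
            frame["x"] = emb2d.points[:, 0]
            frame["y"] = emb2d.points[:, 1]
            frame.to_csv(tsne_path, sep="\t", index=False)
            plot_embedding(emb2d, plot_path, color_by=config.analysis["group_by"])
            reps = representative_frames(embedding, group_by=config.analysis["group_by"])
            Path(reps_path).write_text(json.dumps(reps, indent=2))

        runner.run("analyze", analyze_key,
                   [report_path, tsne_path, plot_path, reps_path], _analyze)
    except Exception:
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(outdir / "manifest.partial.json")
        log.error("pipeline aborted in stage '%s'", stage)
        raise

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest
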