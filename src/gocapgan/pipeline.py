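"""End-to-end pipeline: simulate/ingest -> GAN training -> feature extraction
-> class selection -> classifier -> repeated-CV evaluation.

Each stage writes its artifacts plus a ``<stage>.done`` marker carrying the
resolved-configuration hash, so a rerun with the same configuration resumes
after the last completed stage and a changed configuration invalidates
downstream stages.  Every random choice derives from the single run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import seqio
from .evalmetrics import evaluate_cv, plan_repeated_kfold
from .funcpred import (ClassifierConfig, FeatureMatrix, build_label_matrix,
                       extract_features, select_classes, train_classifier)
from .gan import (GanConfig, build_discriminator, build_generator,
                  load_checkpoint, train_gan)
from .synthetic import SyntheticDesign, generate_corpus

__all__ = ["EvalConfig", "RunConfig", "run_pipeline", "desk_gan_config"]

log = logging.getLogger("gocapgan")

STAGES = ("data", "train-gan", "extract-features", "select-classes",
          "train-classifier", "evaluate")


def desk_gan_config(seed: int = 0, **overrides) -> GanConfig:
    """Desk-scale GAN: narrow model, two epochs — minutes on one CPU core."""
    base = dict(
        channels=16, capsule_conv_channels=16, primary_capsule_dim=8,
        out_capsules=16, out_capsule_dim=8, epochs=2, seq_len=160, seed=seed,
    )
    base.update(overrides)
    return GanConfig(**base)


@dataclass
class EvalConfig:
    k: int = 3
    repeats: int = 5
    min_count: int = 16
    top_k: int = 25
    mode: str = "micro"
    feature_tap: str = "lengths"
    max_residues: int = 2000


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    gan: GanConfig = field(default_factory=lambda: desk_gan_config())
    design: SyntheticDesign = field(default_factory=SyntheticDesign)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    fasta: str | None = None          # ingest instead of simulating
    annotations: str | None = None
    seed: int = 0

    def __post_init__(self):
        # one run seed fans out to every stage deterministically
        self.gan.seed = (self.seed * 7919 + 1) % (2**31)
        self.design.seed = (self.seed * 7919 + 2) % (2**31)
        self.classifier.seed = (self.seed * 7919 + 3) % (2**31)

    def to_dict(self) -> dict:
        return {
            "gan": self.gan.to_dict(),
            "design": self.design.to_dict(),
            "classifier": asdict(self.classifier),
            "evaluation": asdict(self.evaluation),
            "fasta": self.fasta,
            "annotations": self.annotations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            gan=GanConfig.from_dict(d.get("gan", {})),
            design=SyntheticDesign.from_dict(d.get("design", {})),
            classifier=ClassifierConfig(**{
                k: v for k, v in d.get("classifier", {}).items()
                if k in ClassifierConfig.__dataclass_fields__}),
            evaluation=EvalConfig(**{
                k: v for k, v in d.get("evaluation", {}).items()
                if k in EvalConfig.__dataclass_fields__}),
            fasta=d.get("fasta"),
            annotations=d.get("annotations"),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage_done(out_dir: Path, stage: str, cfg_hash: str) -> bool:
    marker = out_dir / f"{stage}.done"
    return marker.exists() and marker.read_text().strip() == cfg_hash


def _mark_done(out_dir: Path, stage: str, cfg_hash: str) -> None:
    (out_dir / f"{stage}.done").write_text(cfg_hash)


def run_pipeline(config: RunConfig, out_dir, resume: bool = True,
                 skip_gan_checkpoint=None) -> Path:
    """Execute all stages into ``out_dir``; returns the run directory.

    ``skip_gan_checkpoint`` reuses an existing critic checkpoint instead of
    training the GAN (stage isolation / ablation).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    (out_dir / "run.json").write_text(json.dumps(
        {"seed": config.seed, "config_hash": cfg_hash}, indent=2))
    timings = {}

    def stage(name):
        done = resume and _stage_done(out_dir, name, cfg_hash)
        log.info("stage %s: %s", name, "cached" if done else "running")
        return done

    t0 = time.time()
    # -- data ----------------------------------------------------------------
    fasta_path = out_dir / "corpus.fasta"
    ann_path = out_dir / "annotations.tsv"
    if not stage("data"):
        if config.fasta is not None:
            records = seqio.read_fasta(config.fasta)
            records, n_removed = seqio.filter_by_length(
                records, config.evaluation.max_residues)
            log.info("length filter removed %d records", n_removed)
            seqio.write_fasta(records, fasta_path)
            if config.annotations is None:
                raise ValueError("an annotation table is required with --fasta")
            table = seqio.read_annotations(
                config.annotations, known_accessions={r.accession for r in records})
            seqio.write_annotations(table.pairs, ann_path)
        else:
            generate_corpus(config.design, out_dir)
        _mark_done(out_dir, "data", cfg_hash)
    records = seqio.read_fasta(fasta_path)
    records, _ = seqio.filter_by_length(records, config.evaluation.max_residues)
    table = seqio.read_annotations(ann_path)
    timings["data"] = time.time() - t0

    # -- train-gan -----------------------------------------------------------
    t0 = time.time()
    gan_dir = out_dir / "gan"
    final_ck = gan_dir / f"checkpoint_epoch{config.gan.epochs}.npz"
    if config.gan.epochs == 0:
        final_ck = gan_dir / "checkpoint_init.npz"
    if skip_gan_checkpoint is not None:
        final_ck = Path(skip_gan_checkpoint)
        log.info("reusing critic checkpoint %s", final_ck)
    elif not stage("train-gan"):
        gen = build_generator(config.gan)
        disc = build_discriminator(config.gan)
        batch = seqio.encode_batch(records, seq_len=config.gan.seq_len)
        state = train_gan(gen, disc, batch, config.gan, out_dir=gan_dir)
        (gan_dir / "history.json").write_text(json.dumps({
            "critic_losses": state.critic_losses,
            "gen_losses": state.gen_losses,
            "gp_values": state.gp_values,
            "steps": state.step,
        }))
        _mark_done(out_dir, "train-gan", cfg_hash)
    timings["train-gan"] = time.time() - t0

    # -- extract-features ----------------------------------------------------
    t0 = time.time()
    feat_path = out_dir / "features.tsv"
    if not stage("extract-features"):
        _, disc, _ = load_checkpoint(final_ck)
        batch = seqio.encode_batch(records, seq_len=disc.config.seq_len)
        features = extract_features(disc, batch, tap=config.evaluation.feature_tap)
        features.write_tsv(feat_path)
        _mark_done(out_dir, "extract-features", cfg_hash)
    features = FeatureMatrix.read_tsv(feat_path)
    timings["extract-features"] = time.time() - t0

    # -- select-classes ------------------------------------------------------
    t0 = time.time()
    classes_path = out_dir / "classes.txt"
    if not stage("select-classes"):
        sel = select_classes(table, config.evaluation.min_count,
                             config.evaluation.top_k)
        classes_path.write_text("".join(f"{go}\n" for go in sel.classes))
        (out_dir / "class_selection.json").write_text(json.dumps(
            {"n_eligible": sel.n_eligible, "selected": sel.classes}, indent=2))
        _mark_done(out_dir, "select-classes", cfg_hash)
    classes = classes_path.read_text().split()
    timings["select-classes"] = time.time() - t0

    # -- train-classifier ----------------------------------------------------
    t0 = time.time()
    labels = build_label_matrix(records, table, classes)
    labels.write_tsv(out_dir / "labels.tsv")
    clf_path = out_dir / "classifier.npz"
    if not stage("train-classifier"):
        model = train_classifier(features, labels, config.classifier)
        model.save(clf_path)
        _mark_done(out_dir, "train-classifier", cfg_hash)
    timings["train-classifier"] = time.time() - t0

    # -- evaluate ------------------------------------------------------------
    t0 = time.time()
    if not stage("evaluate"):
        plan = plan_repeated_kfold(labels.n, config.evaluation.k,
                                   config.evaluation.repeats,
                                   seed=(config.seed * 7919 + 4) % (2**31))
        report = evaluate_cv(features, labels, plan, config.classifier,
                             mode=config.evaluation.mode)
        report.write(tsv_path=out_dir / "folds.tsv",
                     json_path=out_dir / "metrics.json")
        _mark_done(out_dir, "evaluate", cfg_hash)
    timings["evaluate"] = time.time() - t0

    (out_dir / "timings.json").write_text(json.dumps(
        {k: round(v, 3) for k, v in timings.items()}, indent=2))
    return out_dir
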