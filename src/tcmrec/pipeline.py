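"""End-to-end orchestration: cohort -> QC -> tokens -> embeddings ->
(optional GAN augmentation) -> transformer training -> time-sliced report.

Every stage writes its artifacts under one output directory together with a
manifest recording the configuration hash and seed, so a rerun with the same
configuration reproduces the same artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluate as ev
from .embed import EmbedConfig, EmbeddingMatrix, EmbeddingModel, train_embeddings, vectorize
from .features import PatientRecord, extract_tokens, qc_filter, write_records_jsonl
from .gan import GanConfig, augment_dataset, train_gan
from .model import TrainConfig, TransformerConfig, train_model
from .ontology import DrugOntology
from .synth import CohortConfig, corrupt_records, generate_cohort, generate_ontology

__all__ = ["PipelineConfig", "build_dataset", "label_vector", "run_pipeline",
           "train_test_split_records"]


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    embed: EmbedConfig = field(default_factory=EmbedConfig)
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    gan: GanConfig = field(default_factory=GanConfig)
    augment: bool = False
    cutoffs: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 168.0)
    train_cutoffs: tuple[float, ...] | None = None  # default: same as cutoffs
    holdout_frac: float = 0.10
    include_prior_orders: bool = True
    seed: int = 0

    def __post_init__(self):
        # one global seed propagated into every stochastic stage
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        self.embed = dataclasses.replace(self.embed, seed=self.seed)
        self.train = dataclasses.replace(self.train, seed=self.seed)
        self.gan = dataclasses.replace(self.gan, seed=self.seed)

    @classmethod
    def desk_scale(cls, seed: int = 0, **kw) -> "PipelineConfig":
        cohort = kw.pop("cohort", CohortConfig())
        return cls(
            cohort=cohort,
            embed=EmbedConfig(vector_size=32, epochs=25),
            transformer=TransformerConfig.desk_scale(n_labels=cohort.n_category1),
            train=TrainConfig.desk_scale(),
            gan=GanConfig.desk_scale(),
            seed=seed,
            **kw,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sub = {
            "cohort": CohortConfig, "embed": EmbedConfig,
            "transformer": TransformerConfig, "train": TrainConfig,
            "gan": GanConfig,
        }
        kw = {}
        for key, val in raw.items():
            if key in sub:
                kw[key] = sub[key](**val)
            elif key in ("cutoffs", "train_cutoffs") and val is not None:
                kw[key] = tuple(float(v) for v in val)
            else:
                kw[key] = val
        return cls(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def label_vector(order_drug_ids, onto: DrugOntology, label_categories: list[str],
                 level: str = "category1") -> np.ndarray:
    """Binary target over the label space from one reference prescription."""
    cats = onto.rollup(set(order_drug_ids), level=level)
    index = {c: i for i, c in enumerate(label_categories)}
    y = np.zeros(len(label_categories))
    for c in cats:
        if c in index:
            y[index[c]] = 1.0
    return y


def build_dataset(
    records: list[PatientRecord],
    onto: DrugOntology,
    embedding: EmbeddingModel,
    label_categories: list[str],
    cutoffs: tuple[float, ...],
    max_num_tokens: int,
    include_prior_orders: bool = True,
) -> list[tuple[EmbeddingMatrix, np.ndarray]]:
    """One (embedding matrix, label vector) sample per (record, cutoff) pair
    for which the record carries a reference order at the cutoff."""
    out = []
    for r in records:
        for cutoff in cutoffs:
            order = r.order_at(cutoff)
            if order is None:
                continue
            seq = extract_tokens(r, cutoff, include_prior_orders=include_prior_orders)
            em = vectorize(seq, embedding, max_num_tokens)
            out.append((em, label_vector(order.drug_ids, onto, label_categories)))
    return out


def train_test_split_records(
    records: list[PatientRecord], holdout_frac: float, seed: int,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    n = len(records)
    n_test = max(1, int(round(holdout_frac * n)))
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [records[i] for i in range(n) if i not in test_idx]
    test = [records[i] for i in range(n) if i in test_idx]
    return train, test


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline, writing artifacts and a manifest.

    Returns a summary dict with the paths written and the test-set report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                      "config": cfg.to_dict(), "stages": []}

    onto = generate_ontology(cfg.cohort)
    onto.to_csv(outdir / "ontology.csv")
    records = generate_cohort(cfg.cohort, onto)
    records = corrupt_records(records, cfg.cohort)
    write_records_jsonl(records, outdir / "records.jsonl")
    manifest["stages"].append({"stage": "synth", "n_records": len(records)})

    kept, discarded = qc_filter(records)
    manifest["stages"].append({
        "stage": "qc", "n_kept": len(kept), "n_discarded": len(discarded),
        "reasons": sorted({reason for _, reason in discarded}),
    })

    train_recs, test_recs = train_test_split_records(kept, cfg.holdout_frac, cfg.seed)
    train_cutoffs = cfg.train_cutoffs or cfg.cutoffs
    corpus = [
        extract_tokens(r, max(train_cutoffs),
                       include_prior_orders=cfg.include_prior_orders)
        for r in train_recs
    ]
    embedding = train_embeddings(corpus, cfg.embed)
    embedding.save_word2vec(outdir / "embeddings.w2v.txt")
    manifest["stages"].append({"stage": "embed", "vocab_size": len(embedding.vocabulary)})

    label_categories = onto.category1_ids()
    dataset = build_dataset(train_recs, onto, embedding, label_categories,
                            train_cutoffs, cfg.transformer.max_num_tokens,
                            cfg.include_prior_orders)

    if cfg.augment:
        G, D, gan_history = train_gan([em for em, _ in dataset], cfg.gan)
        augmented = augment_dataset(dataset, G, seed=cfg.seed)
        dataset = [(s.x, s.y) for s in augmented]
        manifest["stages"].append({
            "stage": "gan", "epochs_run": len(gan_history),
            "final_d_balanced_accuracy": gan_history[-1]["d_balanced_accuracy"],
            "n_samples_after_augmentation": len(dataset),
        })

    model, history = train_model(dataset, cfg.transformer, cfg.train)
    model.save(outdir / "model")
    with open(outdir / "training_log.csv", "w") as fh:
        fh.write("epoch,train_loss\n")
        for h in history:
            fh.write(f"{h['epoch']},{h['train_loss']}\n")
    manifest["stages"].append({"stage": "train", "epochs": len(history),
                               "final_loss": history[-1]["train_loss"]})

    report_test = ev.evaluate_timeline(
        model, test_recs, onto, embedding, label_categories,
        cutoffs=cfg.cutoffs, include_prior_orders=cfg.include_prior_orders)
    report_train = ev.evaluate_timeline(
        model, train_recs, onto, embedding, label_categories,
        cutoffs=cfg.cutoffs, include_prior_orders=cfg.include_prior_orders)
    report_test.to_csv(outdir / "report_test.csv", index=False)
    report_train.to_csv(outdir / "report_train.csv", index=False)
    (outdir / "report.txt").write_text(ev.render_table(report_train, report_test) + "\n")
    manifest["stages"].append({"stage": "evaluate",
                               "n_test_records": len(test_recs)})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"outdir": str(outdir), "manifest": manifest,
            "report_train": report_train, "report_test": report_test}
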