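"""High-level entry points tying the modules into the full mapping workflow.

This package is used from Python (see ``examples/``): these functions are the
equivalent of a command-line surface — generate a corpus, train, evaluate,
cross-validate, run the baseline, suggest mappings for unlabeled fields, and
plot the embedding — each reading/writing ordinary files and all reproducible
from one top-level seed.  Per-stage seeds are derived deterministically from
that master seed so no two stages share a random stream by accident.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .baseline import evaluate_baseline
from .encoding import concatenate_fields, encode_batch
from .evaluation import EvalReport, cross_validate, evaluate_holdout, pca_project
from .io import Corpus, normalize_corpus, read_corpus, write_corpus
from .knn import DEFAULT_K, ReferenceIndex, build_index, suggest
from .pipeline import FittedPipeline, fit_encoder
from .siamese import ModelConfig, TrainedEncoder, embed_batch
from .synth import GroundTruth, SynthConfig, generate_corpus

__all__ = [
    "RunConfig",
    "derive_seed",
    "run_synth",
    "run_train",
    "run_evaluate",
    "run_crossval",
    "run_baseline",
    "suggest_fields",
    "plot_embedding",
]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """One serializable bundle of every tunable in the workflow."""

    seed: int = 0
    test_fraction: float = 0.2
    k: int = DEFAULT_K
    folds: int = 5
    n_same: int = 20
    n_diff: int = 20
    max_len_cap: int | None = None
    lookup_dim: int = 256
    recurrent_units: int = 64
    embedding_dim: int = 32
    epochs: int = 3
    batch_size: int = 64
    learning_rate: float = 1e-3
    distance_scale: float = 4.0
    loss: str = "bce"

    def model_template(self, stage: str = "train") -> ModelConfig:
        # vocab_size/max_len are data-dependent placeholders filled by fit_encoder
        return ModelConfig(
            vocab_size=1,
            max_len=1,
            lookup_dim=self.lookup_dim,
            recurrent_units=self.recurrent_units,
            embedding_dim=self.embedding_dim,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=derive_seed(self.seed, stage),
            distance_scale=self.distance_scale,
            loss=self.loss,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_synth(config: SynthConfig, out_dir: str | Path) -> GroundTruth:
    """Generate a corpus and write it (CSV) with a ground-truth sidecar (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt = generate_corpus(config)
    write_corpus(gt.corpus, out_dir / "corpus.csv")
    sidecar = {
        "class_labels": gt.class_labels,
        "template_ids": gt.template_ids,
        "config": {**asdict(gt.config)},
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return gt


def run_train(corpus: Corpus, config: RunConfig) -> FittedPipeline:
    """Train the encoder on a labeled corpus under the workflow seed policy."""
    return fit_encoder(
        corpus,
        model_config=config.model_template("train"),
        n_same=config.n_same,
        n_diff=config.n_diff,
        seed=derive_seed(config.seed, "pairs"),
        max_len_cap=config.max_len_cap,
    )


def run_evaluate(corpus: Corpus, config: RunConfig, out: str | Path | None = None) -> EvalReport:
    """Stratified-holdout evaluation; optionally writes the report as JSON."""
    report = evaluate_holdout(
        corpus,
        model_config=config.model_template("train"),
        test_fraction=config.test_fraction,
        seed=config.seed,
        k=config.k,
        n_same=config.n_same,
        n_diff=config.n_diff,
        max_len_cap=config.max_len_cap,
    )
    if out is not None:
        Path(out).write_text(json.dumps(report.to_dict(), indent=1, default=float))
    return report


def run_crossval(corpus: Corpus, config: RunConfig) -> list[EvalReport]:
    return cross_validate(
        corpus,
        folds=config.folds,
        model_config=config.model_template("train"),
        seed=config.seed,
        k=config.k,
        n_same=config.n_same,
        n_diff=config.n_diff,
        max_len_cap=config.max_len_cap,
    )


def run_baseline(corpus: Corpus, config: RunConfig, out: str | Path | None = None) -> EvalReport:
    """TF-IDF + boosted-trees comparison under the identical split seed."""
    report = evaluate_baseline(corpus, test_fraction=config.test_fraction, seed=config.seed)
    if out is not None:
        Path(out).write_text(json.dumps(report.to_dict(), indent=1, default=float))
    return report


def suggest_fields(
    encoder: TrainedEncoder,
    index: ReferenceIndex,
    queries: Corpus,
    k: int = DEFAULT_K,
) -> list[dict]:
    """Rank SDTM-field suggestions for (possibly unlabeled) query fields.

    Returns one JSON-serializable dict per query with the ranked neighbors
    and the three decision-mode answers.
    """
    queries = normalize_corpus(queries)
    seqs = encode_batch(
        (concatenate_fields(r) for r in queries), encoder.vocab, encoder.config.max_len
    )
    out = []
    for rec, emb in zip(queries, embed_batch(encoder, seqs)):
        sg = suggest(index, emb, k=k)
        out.append(
            {
                "form_oid": rec.form_oid,
                "field_oid": rec.field_oid,
                "neighbors": [
                    {"label": lab, "distance": dist, "record_ref": ref}
                    for lab, dist, ref in sg.neighbors
                ],
                "nearest_label": sg.nearest_label,
                "majority_label": sg.majority_label,
                "top_k_labels": sorted(sg.top_k_labels),
            }
        )
    return out


def plot_embedding(
    encoder: TrainedEncoder, corpus: Corpus, out_path: str | Path
) -> None:
    """2-D PCA scatter of the corpus embedding, colored by SDTM target."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    corpus = normalize_corpus(corpus)
    seqs = encode_batch(
        (concatenate_fields(r) for r in corpus), encoder.vocab, encoder.config.max_len
    )
    emb = embed_batch(encoder, seqs)
    xy = pca_project(emb, dims=2)
    labels = [r.label for r in corpus]
    fig, ax = plt.subplots(figsize=(7, 6))
    for lab in sorted(set(labels)):
        mask = [l == lab for l in labels]
        ax.scatter(xy[mask, 0], xy[mask, 1], s=8, label=lab, alpha=0.7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=6, markerscale=1.5, ncol=2)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
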