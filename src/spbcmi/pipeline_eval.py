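"""Feature fusion, cross-validated evaluation, and the evaluation metrics.

Each candidate pair is represented by the concatenation
[circ_seq | circ_struct | mir_seq | mir_struct] (sequence features from the
masked-LM encoder, structural features from the network factorization);
ablation modes keep only one view. Evaluation is 5-fold cross-validation
(or a single 80/20 holdout): within every fold the interaction graph is
rebuilt from that fold's training positives only, so no test edge can leak
into the structural embedding, and the classifier sees only training pairs.
The sequence model is trained once on the unlabelled sequence corpus; it
never sees interaction labels.

All metrics (AUC, AUPR, ACC, MCC, F1) are computed here from first
principles: AUC via the midrank statistic, AUPR by interpolation-free step
integration of the precision-recall curve, the rest from the thresholded
confusion matrix.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from . import gbdt, graph_hope, seq_lm
from .io_corpus import InteractionSet, SequenceRecord
from .tokenizer import Vocabulary, tokenize_document

FeatureMode = Literal["both", "seq", "struct"]


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the midrank (Mann-Whitney) statistic."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step integration.

    AP = sum_i (R_i - R_{i-1}) P_i over descending score thresholds, with
    tied scores grouped at one threshold (no interpolation).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUPR undefined: only one class present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # last index of every tied-score group
    boundary = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[boundary]
    fp = np.cumsum(1 - y)[boundary]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """(fpr, tpr, thresholds) at every distinct score, descending."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    boundary = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[boundary]
    fp = np.cumsum(1 - y)[boundary]
    n_pos, n_neg = int(labels.sum()), int(len(labels) - labels.sum())
    tpr = np.r_[0.0, tp / max(n_pos, 1)]
    fpr = np.r_[0.0, fp / max(n_neg, 1)]
    thresholds = np.r_[np.inf, s[boundary]]
    return fpr, tpr, thresholds


def pr_curve(scores: np.ndarray, labels: np.ndarray):
    """(recall, precision) points at every distinct score, descending."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    boundary = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[boundary]
    fp = np.cumsum(1 - y)[boundary]
    n_pos = int(labels.sum())
    recall = np.r_[0.0, tp / max(n_pos, 1)]
    precision = np.r_[1.0, tp / (tp + fp)]
    return recall, precision


def confusion(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5):
    pred = np.asarray(scores, dtype=np.float64) >= threshold
    labels = np.asarray(labels).astype(bool)
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return tp, fp, fn, tn


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """AUC, AUPR, ACC, MCC and F1 for one scored test set.

    With a single-class label vector the ranking metrics are undefined and
    reported as NaN (with a warning); threshold metrics are still computed.
    MCC is defined as 0 when a confusion-matrix marginal is zero.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    tp, fp, fn, tn = confusion(scores, labels, threshold)
    n = tp + fp + fn + tn
    acc = (tp + tn) / n
    f1_denom = 2 * tp + fp + fn
    if f1_denom == 0:
        warnings.warn("F1 undefined (no positive predictions or labels): returning 0")
        f1 = 0.0
    else:
        f1 = 2 * tp / f1_denom
    mcc_denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_denom == 0:
        warnings.warn("MCC undefined (zero marginal): returning 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(mcc_denom))
    try:
        auc = roc_auc(scores, labels)
        aupr = average_precision(scores, labels)
    except ValueError:
        warnings.warn("single-class labels: AUC/AUPR reported as NaN")
        auc = aupr = float("nan")
    return {"AUC": auc, "AUPR": aupr, "ACC": acc, "MCC": float(mcc), "F1": f1}


# ---------------------------------------------------------------------------
# fusion


@dataclass
class PairFeature:
    """Fused feature vector of one candidate pair."""

    circ_id: str
    mir_id: str
    vector: np.ndarray
    label: int


def fuse(
    seq_feats: dict[str, np.ndarray] | None,
    struct_feats: dict[str, np.ndarray] | None,
    pairs: Sequence[tuple[str, str, int]],
    mode: FeatureMode = "both",
) -> list[PairFeature]:
    """Concatenate per-molecule features into per-pair vectors.

    Ordering is [circ_seq | circ_struct | mir_seq | mir_struct]; ablation
    modes drop one view. A pair whose id lacks a required feature is an
    error naming the id.
    """
    out: list[PairFeature] = []
    for c, m, lab in pairs:
        parts = []
        for rid in (c, m):
            if mode in ("both", "seq"):
                if seq_feats is None or rid not in seq_feats:
                    raise KeyError(f"missing sequence feature for id {rid!r}")
                parts.append(seq_feats[rid])
            if mode in ("both", "struct"):
                if struct_feats is None or rid not in struct_feats:
                    raise KeyError(f"missing structural feature for id {rid!r}")
                parts.append(struct_feats[rid])
        out.append(PairFeature(circ_id=c, mir_id=m, vector=np.concatenate(parts), label=lab))
    return out


def feature_matrix(pair_feats: Sequence[PairFeature]) -> tuple[np.ndarray, np.ndarray]:
    if not pair_feats:
        return np.zeros((0, 0)), np.zeros(0, dtype=np.int64)
    X = np.stack([p.vector for p in pair_feats])
    y = np.array([p.label for p in pair_feats], dtype=np.int64)
    return X, y


# ---------------------------------------------------------------------------
# splitting


def kfold_split(
    n_pairs: int, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition into (train_idx, test_idx) tuples.

    Folds are disjoint, differ in size by at most one, and cover all
    indices.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_pairs < k:
        raise ValueError(f"cannot split {n_pairs} pairs into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_pairs)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, test))
    return out


def holdout_split(n_pairs: int, test_fraction: float = 0.2, seed: int = 0):
    """Single shuffled train/test split (default 80/20)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_pairs)
    n_test = max(1, int(round(test_fraction * n_pairs)))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything tunable about one experiment, with the defaults used
    throughout the package."""

    seed: int = 0
    k: int = 3
    # sequence language model
    lm_layers: int = 2
    lm_heads: int = 4
    lm_d_model: int = 64
    lm_d_ff: int = 128
    lm_d_out: int = 64
    lm_dropout: float = 0.1
    lm_mask_rate: float = 0.15
    lm_epochs: int = 3
    lm_learning_rate: float = 1e-3
    lm_weight_decay: float = 0.01
    lm_batch_size: int = 16
    retrain_lm_per_fold: bool = False
    # structural embedding
    hope_dim: int = 32
    beta_fraction: float = 0.5
    proximity: str = "katz"
    # classifier
    gbdt_stages: int = 300
    gbdt_learning_rate: float = 0.1
    gbdt_max_depth: int = 3
    gbdt_min_samples_leaf: int = 5
    # evaluation
    folds: int = 5
    features: FeatureMode = "both"
    threshold: float = 0.5

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def encoder_config(self, vocab_size: int) -> seq_lm.EncoderConfig:
        return seq_lm.EncoderConfig(
            vocab_size=vocab_size,
            n_layers=self.lm_layers,
            n_heads=self.lm_heads,
            d_model=self.lm_d_model,
            d_ff=self.lm_d_ff,
            d_out=self.lm_d_out,
            dropout=self.lm_dropout,
            mask_rate=self.lm_mask_rate,
            k=self.k,
        )

    def optimizer_settings(self) -> seq_lm.OptimizerSettings:
        return seq_lm.OptimizerSettings(
            learning_rate=self.lm_learning_rate,
            weight_decay=self.lm_weight_decay,
            batch_size=self.lm_batch_size,
        )


# ---------------------------------------------------------------------------
# evaluation harness


@dataclass
class FoldResult:
    metrics: dict[str, float]
    train_pairs: list[tuple[str, str, int]]
    test_pairs: list[tuple[str, str, int]]
    train_hash: str
    scores: np.ndarray
    labels: np.ndarray


@dataclass
class EvalReport:
    """Per-fold metrics plus their mean and (population) variance."""

    folds: list[FoldResult]
    mean: dict[str, float] = field(default_factory=dict)
    variance: dict[str, float] = field(default_factory=dict)

    def summarize(self) -> None:
        names = self.folds[0].metrics.keys()
        self.mean = {
            n: float(np.mean([f.metrics[n] for f in self.folds])) for n in names
        }
        self.variance = {
            n: float(np.var([f.metrics[n] for f in self.folds])) for n in names
        }

    def to_dict(self) -> dict:
        return {
            "folds": [f.metrics for f in self.folds],
            "mean": self.mean,
            "variance": self.variance,
            "fold_train_hashes": [f.train_hash for f in self.folds],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def training_input_hash(
    train_pairs: Sequence[tuple[str, str, int]],
    graph_edges: Sequence[tuple[str, str]],
    mode: str,
) -> str:
    """Digest of everything label-bearing that enters fold training.

    Covers the labelled training pairs and the graph edges used for the
    structural embedding; a test pair can influence the fold only by
    appearing here.
    """
    h = hashlib.sha256()
    h.update(mode.encode())
    for c, m, lab in sorted(train_pairs):
        h.update(f"P\t{c}\t{m}\t{lab}\n".encode())
    for c, m in sorted(graph_edges):
        h.update(f"E\t{c}\t{m}\n".encode())
    return h.hexdigest()


def train_sequence_model(
    records: Sequence[SequenceRecord], config: PipelineConfig
) -> tuple[seq_lm.EncoderModel, dict[str, np.ndarray]]:
    """Train the masked LM on the whole (unlabelled) corpus and extract
    one feature vector per molecule."""
    vocab = Vocabulary.build(config.k)
    docs = [tokenize_document(r.seq, vocab, seq_id=r.id) for r in records]
    model = seq_lm.train_mlm(
        docs,
        config.encoder_config(len(vocab)),
        opt=config.optimizer_settings(),
        epochs=config.lm_epochs,
        seed=config.seed,
    )
    ids, mat = seq_lm.extract_features(model, docs)
    return model, dict(zip(ids, mat))


def _fold_run(
    fold_pairs_train: list[tuple[str, str, int]],
    fold_pairs_test: list[tuple[str, str, int]],
    circ_ids: Sequence[str],
    mir_ids: Sequence[str],
    seq_feats: dict[str, np.ndarray] | None,
    config: PipelineConfig,
) -> FoldResult:
    """Train on one fold: graph from training positives, embed, fuse, boost."""
    struct_feats = None
    train_positive_edges = [(c, m) for c, m, lab in fold_pairs_train if lab == 1]
    if config.features in ("both", "struct"):
        graph = graph_hope.build_graph(train_positive_edges, circ_ids, mir_ids)
        struct_feats, _ = graph_hope.embed_graph(
            graph, d=config.hope_dim, beta_fraction=config.beta_fraction,
            proximity=config.proximity,
        )
    Xtr, ytr = feature_matrix(
        fuse(seq_feats, struct_feats, fold_pairs_train, config.features)
    )
    Xte, yte = feature_matrix(
        fuse(seq_feats, struct_feats, fold_pairs_test, config.features)
    )
    model = gbdt.fit(
        Xtr, ytr,
        n_stages=config.gbdt_stages,
        learning_rate=config.gbdt_learning_rate,
        max_depth=config.gbdt_max_depth,
        min_samples_leaf=config.gbdt_min_samples_leaf,
        loss="logistic",
    )
    scores = gbdt.predict_proba(model, Xte)
    metrics = compute_metrics(scores, yte, threshold=config.threshold)
    return FoldResult(
        metrics=metrics,
        train_pairs=list(fold_pairs_train),
        test_pairs=list(fold_pairs_test),
        train_hash=training_input_hash(fold_pairs_train, train_positive_edges, config.features),
        scores=scores,
        labels=yte,
    )


def run_cv(
    dataset: InteractionSet,
    circ_records: Sequence[SequenceRecord],
    mir_records: Sequence[SequenceRecord],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> EvalReport:
    """k-fold cross-validation of the full pipeline.

    The sequence LM (when used) is trained once on all sequences -- it
    sees no interaction labels -- unless ``retrain_lm_per_fold`` is set.
    Per fold the graph embedding and classifier are fit from training
    pairs only. ROC/PRC coordinates are written to ``out_dir`` if given.
    """
    circ_ids = [r.id for r in circ_records]
    mir_ids = [r.id for r in mir_records]
    seq_feats = None
    if config.features in ("both", "seq") and not config.retrain_lm_per_fold:
        _, seq_feats = train_sequence_model(list(circ_records) + list(mir_records), config)
    pairs = dataset.pairs
    splits = kfold_split(len(pairs), k=config.folds, seed=config.seed)
    folds: list[FoldResult] = []
    for fold_id, (train_idx, test_idx) in enumerate(splits):
        fold_seq_feats = seq_feats
        if config.features in ("both", "seq") and config.retrain_lm_per_fold:
            fold_cfg = PipelineConfig(**{**asdict(config), "seed": config.seed + fold_id})
            _, fold_seq_feats = train_sequence_model(
                list(circ_records) + list(mir_records), fold_cfg
            )
        res = _fold_run(
            [pairs[i] for i in train_idx],
            [pairs[i] for i in test_idx],
            circ_ids, mir_ids, fold_seq_feats, config,
        )
        folds.append(res)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            fpr, tpr, thr = roc_curve(res.scores, res.labels)
            np.savetxt(out / f"roc_fold{fold_id}.tsv",
                       np.c_[fpr, tpr, thr], delimiter="\t",
                       header="fpr\ttpr\tthreshold", comments="")
            rec, prec = pr_curve(res.scores, res.labels)
            np.savetxt(out / f"prc_fold{fold_id}.tsv",
                       np.c_[rec, prec], delimiter="\t",
                       header="recall\tprecision", comments="")
    report = EvalReport(folds=folds)
    report.summarize()
    if out_dir is not None:
        report.save(Path(out_dir) / "cv_metrics.json")
    return report


def run_holdout(
    dataset: InteractionSet,
    circ_records: Sequence[SequenceRecord],
    mir_records: Sequence[SequenceRecord],
    config: PipelineConfig,
    test_fraction: float = 0.2,
) -> FoldResult:
    """Single 80/20 evaluation with the same leakage discipline as run_cv."""
    circ_ids = [r.id for r in circ_records]
    mir_ids = [r.id for r in mir_records]
    seq_feats = None
    if config.features in ("both", "seq"):
        _, seq_feats = train_sequence_model(list(circ_records) + list(mir_records), config)
    train_idx, test_idx = holdout_split(len(dataset.pairs), test_fraction, config.seed)
    return _fold_run(
        [dataset.pairs[i] for i in train_idx],
        [dataset.pairs[i] for i in test_idx],
        circ_ids, mir_ids, seq_feats, config,
    )


def permute_labels(dataset: InteractionSet, seed: int) -> InteractionSet:
    """Null control: same pairs, labels randomly reassigned."""
    rng = np.random.default_rng(seed)
    labels = dataset.labels()
    perm = rng.permutation(len(labels))
    pairs = [
        (c, m, int(labels[perm[i]])) for i, (c, m, _) in enumerate(dataset.pairs)
    ]
    return InteractionSet(pairs=pairs, provenance=dict(dataset.provenance), seed=dataset.seed)
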