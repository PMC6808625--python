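"""Corpus splitting, rare-class discarding, and minibatch CRF training
with early stopping on development-set entity F1."""
from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .corpus_io import bio_to_entities, entities_to_tags, sentence_spans
from .evaluation import EvalReport, evaluate
from .model import SequenceTagger
from .types import Document, TagSequence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Document-level split fractions; 80/10/10 train/dev/test default."""
    train: float = 0.8
    dev: float = 0.1
    test: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.dev + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train, self.dev, self.test) <= 0:
            raise ValueError("split fractions must be positive")

    @property
    def fractions(self) -> Tuple[float, float, float]:
        return (self.train, self.dev, self.test)


def stratified_split(
    corpus: Sequence[Document], spec: SplitSpec
) -> Tuple[List[Document], List[Document], List[Document]]:
    """Greedy iterative stratification over entity-label mention counts.

    Documents carrying the currently rarest label are assigned first, each
    to the split with the greatest remaining need for that label (ties:
    greatest remaining document capacity, then lowest split index), so each
    label's mentions end up distributed close to the target fractions.
    Deterministic under ``spec.seed``.
    """
    if len(corpus) < 3:
        raise ValueError("need at least as many documents as splits")
    rng = np.random.default_rng(spec.seed)
    docs = list(corpus)
    order = rng.permutation(len(docs))
    docs = [docs[i] for i in order]

    label_counts: List[Dict[str, int]] = []
    totals: Dict[str, int] = {}
    for doc in docs:
        counts: Dict[str, int] = {}
        for ent in doc.entities:
            counts[ent.label] = counts.get(ent.label, 0) + 1
            totals[ent.label] = totals.get(ent.label, 0) + 1
        label_counts.append(counts)

    fracs = spec.fractions
    need = {lab: [f * n for f in fracs] for lab, n in totals.items()}
    cap = [f * len(docs) for f in fracs]
    splits: Tuple[List[Document], ...] = ([], [], [])
    unassigned = set(range(len(docs)))

    def assign(i: int, s: int) -> None:
        splits[s].append(docs[i])
        unassigned.remove(i)
        cap[s] -= 1
        for lab, c in label_counts[i].items():
            need[lab][s] -= c

    while unassigned:
        remaining = {lab: sum(label_counts[i].get(lab, 0) for i in unassigned)
                     for lab in totals}
        remaining = {lab: n for lab, n in remaining.items() if n > 0}
        if not remaining:
            for i in sorted(unassigned):  # entity-free documents
                s = max(range(3), key=lambda s: (cap[s], -s))
                assign(i, s)
            break
        rare = min(remaining, key=lambda lab: (remaining[lab], lab))
        for i in sorted(j for j in unassigned if label_counts[j].get(rare, 0)):
            # weight every label the document carries by the split's
            # remaining relative need, so frequent co-occurring labels
            # stay balanced too
            def score(s: int) -> Tuple[float, float, int]:
                pull = sum(c * need[lab][s] / max(totals[lab], 1)
                           for lab, c in label_counts[i].items())
                return (pull, cap[s], -s)
            s = max(range(3), key=score)
            assign(i, s)

    for name, part in zip(("train", "dev", "test"), splits):
        if not part:
            raise ValueError(f"{name} split is empty; corpus too small")
    return splits


def discard_rare_classes(
    corpus: Sequence[Document], labels_to_drop: Iterable[str]
) -> List[Document]:
    """Remove entities of the given labels (their tokens become O).

    Documents, text and token offsets are untouched.  Labels never seen in
    the corpus are warned about and ignored.
    """
    drop = set(labels_to_drop)
    seen = {e.label for d in corpus for e in d.entities}
    for lab in drop - seen:
        logger.warning("label %r not present in corpus; nothing to discard", lab)
    dropped = 0
    out = []
    for doc in corpus:
        kept = [e for e in doc.entities if e.label not in drop]
        dropped += len(doc.entities) - len(kept)
        out.append(Document(doc.doc_id, doc.text, list(doc.tokens), kept))
    if drop & seen:
        logger.info("discarded %d entity mentions of classes %s",
                    dropped, sorted(drop & seen))
    return out


# ---------------------------------------------------------------------------
# Early stopping
# ---------------------------------------------------------------------------

@dataclass
class EarlyStopping:
    """Pure state machine over the dev-metric sequence.

    Improvement is a strict increase beyond ``tol``; training stops when
    ``patience`` consecutive epochs bring no improvement.  The best epoch's
    checkpoint is what training returns.
    """
    patience: int = 10
    tol: float = 1e-6
    best: float = float("-inf")
    best_epoch: int = 0
    epochs_since_improvement: int = 0
    epoch: int = 0

    def update(self, metric: float) -> bool:
        """Record one epoch's metric; returns True when training should stop."""
        self.epoch += 1
        if metric > self.best + self.tol:
            self.best = metric
            self.best_epoch = self.epoch
            self.epochs_since_improvement = 0
        else:
            self.epochs_since_improvement += 1
        return self.epochs_since_improvement >= self.patience


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class _Sgd:
    def __init__(self, params, lr: float, clip: float) -> None:
        self.params, self.lr, self.clip = params, lr, clip

    def step(self) -> None:
        _clip_global(self.params, self.clip)
        for p in self.params.values():
            if p.grad is not None:
                p.value -= self.lr * p.grad


class _Adam:
    def __init__(self, params, lr: float, clip: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.lr, self.clip = params, lr, clip
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        _clip_global(self.params, self.clip)
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps)


def _clip_global(params, clip: float) -> None:
    if clip <= 0:
        return
    total = np.sqrt(sum(float(np.sum(p.grad ** 2))
                        for p in params.values() if p.grad is not None))
    if total > clip:
        scale = clip / total
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    patience: int = 10
    max_epochs: int = 100
    batch_size: int = 16
    optimizer: str = "sgd"  # sgd | adam
    learning_rate: float = 0.005
    gradient_clip: float = 5.0
    seed: int = 0


@dataclass
class TrainResult:
    model: SequenceTagger
    history: List[dict] = field(default_factory=list)
    best_epoch: int = 0
    best_dev_f1: float = 0.0


def sentences_with_tags(
    docs: Sequence[Document], scheme: str
) -> List[Tuple[list, TagSequence]]:
    """(tokens, tags) pairs, one per sentence, for the training loop."""
    out = []
    for doc in docs:
        tags = entities_to_tags(doc, scheme, expand_boundaries=True).tags
        for lo, hi in sentence_spans(doc):
            if hi > lo:
                out.append((list(doc.tokens[lo:hi]),
                            TagSequence(scheme, tags[lo:hi])))
    return out


def predict_documents(
    model: SequenceTagger, docs: Sequence[Document]
) -> List[Document]:
    """Run the tagger sentence-by-sentence and decode entity spans."""
    out = []
    for doc in docs:
        spans = [(lo, hi) for lo, hi in sentence_spans(doc) if hi > lo]
        tags: List[str] = []
        if spans:
            predicted = model.predict_batch(
                [doc.tokens[lo:hi] for lo, hi in spans])
            for seq in predicted:
                tags.extend(seq.tags)
        entities = bio_to_entities(
            doc.tokens, TagSequence(model.config.scheme, tags), doc.text)
        out.append(Document(doc.doc_id, doc.text, list(doc.tokens), entities))
    return out


def train(
    train_docs: Sequence[Document],
    dev_docs: Sequence[Document],
    model: SequenceTagger,
    config: Optional[TrainConfig] = None,
) -> TrainResult:
    """Minibatch NLL training with early stopping on dev entity F1.

    After every epoch the model tags the dev documents and the entity-level
    micro F1 drives model selection; the parameters of the best epoch are
    restored before returning.  Loss becoming non-finite aborts with
    diagnostics rather than continuing on garbage.
    """
    if not train_docs or not dev_docs:
        raise ValueError("train and dev must be non-empty")
    config = config or TrainConfig()
    scheme = model.config.scheme
    sentences = sentences_with_tags(train_docs, scheme)
    if not sentences:
        raise ValueError("no training sentences")
    rng = np.random.default_rng(config.seed)
    model.reseed_dropout(int(rng.integers(2 ** 31)))
    if config.optimizer == "sgd":
        opt = _Sgd(model.params, config.learning_rate, config.gradient_clip)
    elif config.optimizer == "adam":
        opt = _Adam(model.params, config.learning_rate, config.gradient_clip)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    stopper = EarlyStopping(patience=config.patience)
    best_params: Optional[dict] = None
    history: List[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(sentences))
        epoch_loss = 0.0
        for lo in range(0, len(order), config.batch_size):
            batch = [sentences[i] for i in order[lo:lo + config.batch_size]]
            model.zero_grad()
            loss = model.batch_loss(batch, training=True)
            value = float(loss.value)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (batch of "
                    f"{len(batch)} sentences); lower the learning rate or "
                    "enable gradient clipping")
            loss.backward(np.asarray(1.0 / len(batch)))
            epoch_loss += value
            opt.step()
        dev_pred = predict_documents(model, dev_docs)
        report = evaluate(dev_docs, dev_pred, scheme)
        f1 = report.overall.f1
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / len(sentences),
            "dev_f1": f1,
            "dev_precision": report.overall.precision,
            "dev_recall": report.overall.recall,
        })
        logger.info("epoch %d: loss %.4f dev F1 %.2f", epoch,
                    epoch_loss / len(sentences), f1)
        improved_before = stopper.best
        stop = stopper.update(f1)
        if stopper.best > improved_before:
            best_params = {k: p.value.copy() for k, p in model.params.items()}
        if stop:
            break
    if best_params is not None:
        for k, p in model.params.items():
            p.value = best_params[k]
    return TrainResult(model=model, history=history,
                       best_epoch=stopper.best_epoch,
                       best_dev_f1=max(stopper.best, 0.0))
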