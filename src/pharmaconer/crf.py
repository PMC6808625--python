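"""Linear-chain CRF: the label-sequence-optimization layer.

A path ``y_1..y_n`` over tag set of size L scores

    start[y_1] + sum_i emissions[i, y_i] + sum_i T[y_{i-1}, y_i] + stop[y_n]

Training minimizes the negative log-likelihood ``logZ - score(gold)`` where
``logZ`` is the log partition function computed by the forward algorithm in
log space; decoding is exact Viterbi with deterministic tie-breaking
(lowest tag index wins at every backpointer).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _autodiff as ad
from .types import BIO, BIOES, _split_tag

# Finite stand-in for -inf on forbidden transitions: large enough that no
# forbidden path can win, small enough to keep gradients finite.
NEG_INF = -1.0e4


@dataclass
class CrfParameters:
    """Transition matrix T[y_prev, y_next] plus start/stop score vectors."""
    transitions: np.ndarray
    start: np.ndarray
    stop: np.ndarray

    def __post_init__(self) -> None:
        L = self.transitions.shape[0]
        if self.transitions.shape != (L, L) or self.start.shape != (L,) \
                or self.stop.shape != (L,):
            raise ValueError("inconsistent CRF parameter shapes")
        if not (np.isfinite(self.transitions).all()
                and np.isfinite(self.start).all()
                and np.isfinite(self.stop).all()):
            raise ValueError("non-finite CRF parameters")


def _as_triplet(crf) -> Tuple[ad.Tensor, ad.Tensor, ad.Tensor]:
    if isinstance(crf, CrfParameters):
        return (ad.as_tensor(crf.transitions), ad.as_tensor(crf.start),
                ad.as_tensor(crf.stop))
    return crf  # already (transitions, start, stop) tensors


def crf_partition(
    emissions: Union[np.ndarray, ad.Tensor], crf
) -> ad.Tensor:
    """log Z: log-sum-exp of the scores of all L^n tag paths."""
    e = ad.as_tensor(emissions)
    if e.value.ndim != 2 or e.value.shape[0] < 1:
        raise ValueError("emissions must be (n>=1, L)")
    if not np.isfinite(e.value).all():
        raise ValueError("non-finite emissions")
    trans, start, stop = _as_triplet(crf)
    n, L = e.value.shape
    alpha = start + e[0]
    for t in range(1, n):
        # alpha'[y] = logsumexp_{y'}(alpha[y'] + T[y',y]) + e[t,y]
        scores = alpha.reshape(L, 1) + trans
        alpha = ad.logsumexp(scores, axis=0) + e[t]
    return ad.logsumexp(alpha + stop)


def path_score(
    emissions: Union[np.ndarray, ad.Tensor], crf, tags: Sequence[int]
) -> ad.Tensor:
    """Score of one explicit tag path (indices into the tag set)."""
    e = ad.as_tensor(emissions)
    n, L = e.value.shape
    if len(tags) != n:
        raise ValueError(f"{len(tags)} tags for {n} tokens")
    if any(t < 0 or t >= L for t in tags):
        raise ValueError("tag index outside label set")
    trans, start, stop = _as_triplet(crf)
    idx = np.asarray(tags)
    score = start[idx[0]] + e[(np.arange(n), idx)].sum() + stop[idx[-1]]
    if n > 1:
        score = score + trans[(idx[:-1], idx[1:])].sum()
    return score


def crf_loss(
    emissions: Union[np.ndarray, ad.Tensor], crf, tags: Sequence[int]
) -> ad.Tensor:
    """Negative log-likelihood of the gold path; >= 0 up to float tolerance."""
    return crf_partition(emissions, crf) - path_score(emissions, crf, tags)


def viterbi_decode(
    emissions: np.ndarray, crf: CrfParameters
) -> Tuple[List[int], float]:
    """Highest-scoring tag path and its score (exact, deterministic).

    ``np.argmax`` returns the lowest index among ties, which fixes the
    tie-break rule at every backpointer.
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    n, L = emissions.shape
    if n < 1:
        raise ValueError("need at least one token")
    delta = crf.start + emissions[0]
    backptr = np.zeros((n, L), dtype=np.intp)
    for t in range(1, n):
        scores = delta[:, None] + crf.transitions  # (prev, next)
        backptr[t] = np.argmax(scores, axis=0)
        delta = scores[backptr[t], np.arange(L)] + emissions[t]
    delta = delta + crf.stop
    best_last = int(np.argmax(delta))
    best_score = float(delta[best_last])
    path = [best_last]
    for t in range(n - 1, 0, -1):
        path.append(int(backptr[t, path[-1]]))
    path.reverse()
    return path, best_score


# ---------------------------------------------------------------------------
# Tag inventories and scheme-validity masks
# ---------------------------------------------------------------------------

def tag_inventory(entity_labels: Sequence[str], scheme: str) -> List[str]:
    """Ordered full tag set for a label inventory: O first, then per label
    the scheme's prefixed tags."""
    prefixes = ("B", "I") if scheme == BIO else ("B", "I", "E", "S")
    tags = ["O"]
    for label in entity_labels:
        tags.extend(f"{p}-{label}" for p in prefixes)
    return tags


def transition_masks(
    tags: Sequence[str], scheme: str
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive masks (0 allowed / NEG_INF forbidden) enforcing the scheme
    grammar on transitions, start and stop, so every decoded sequence is
    decodable to entities."""
    L = len(tags)
    parsed = [_split_tag(t) for t in tags]
    trans = np.zeros((L, L))
    start = np.zeros(L)
    stop = np.zeros(L)
    for j, (p, lab) in enumerate(parsed):
        if (scheme == BIO and p == "I") or (scheme == BIOES and p in ("I", "E")):
            start[j] = NEG_INF
    for i, (p, lab) in enumerate(parsed):
        if scheme == BIOES and p in ("B", "I"):
            stop[i] = NEG_INF
    for i, (pi, li) in enumerate(parsed):
        for j, (pj, lj) in enumerate(parsed):
            trans[i, j] = 0.0 if _allowed(pi, li, pj, lj, scheme) else NEG_INF
    return trans, start, stop


def _allowed(pi: str, li: Optional[str], pj: str, lj: Optional[str],
             scheme: str) -> bool:
    if scheme == BIO:
        if pj == "I":
            return pi in ("B", "I") and li == lj
        return True  # O and B reachable from anything
    # BIOES
    if pi in ("B", "I"):  # an entity is open and must continue
        return pj in ("I", "E") and li == lj
    # pi in O/E/S: entity closed, only openers or O may follow
    return pj in ("O", "B", "S")
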