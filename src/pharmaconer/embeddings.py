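"""Token/character vocabularies and plain-text embedding loading.

Supports the common text vector formats (word2vec text with a ``count dim``
header, GloVe and fastText ``.vec`` without one); gzip-compressed files are
read transparently.  Out-of-vocabulary tokens map to a single UNK row — no
subword composition.
"""
from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .types import Document, FormatError

logger = logging.getLogger(__name__)

UNK = "<UNK>"
PAD = "<PAD>"


def load_pretrained(path) -> Tuple[Dict[str, np.ndarray], int]:
    """Load a plain-text embedding file into a word -> float32 vector map.

    A leading "count dim" header is auto-detected and skipped.  Malformed
    lines (wrong arity, unparsable floats) are skipped with a logged count;
    if more than half of the lines are malformed the file is rejected.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    vectors: Dict[str, np.ndarray] = {}
    dim: Optional[int] = None
    skipped = 0
    total = 0
    with opener(path, "rt", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split(" ")
            parts = [p for p in parts if p]
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    int(parts[0]), int(parts[1])
                    continue  # header line
                except ValueError:
                    pass
            total += 1
            word, values = parts[0], parts[1:]
            if dim is None and len(values) >= 1:
                dim = len(values)
            if len(values) != dim:
                skipped += 1
                continue
            try:
                vec = np.asarray(values, dtype=np.float32)
            except ValueError:
                skipped += 1
                continue
            vectors[word] = vec
    if not vectors:
        raise FormatError(f"{path}: no vectors found")
    if skipped:
        logger.warning("%s: skipped %d malformed lines", path, skipped)
        if skipped > total / 2:
            raise FormatError(
                f"{path}: {skipped}/{total} lines malformed — inconsistent "
                "vector dimensions"
            )
    return vectors, int(dim)


def write_embeddings(mapping: Dict[str, np.ndarray], path, header: bool = True) -> None:
    """Write a mapping back to word2vec text format (round-trip helper)."""
    words = list(mapping)
    dim = len(next(iter(mapping.values()))) if words else 0
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(words)} {dim}\n")
        for w in words:
            vals = " ".join(repr(float(v)) for v in mapping[w])
            fh.write(f"{w} {vals}\n")


class TokenVocabulary:
    """Ordered token inventory with UNK/PAD rows and an embedding matrix.

    The vocabulary is the union of the training tokens and the pretrained
    words (so pretrained coverage survives training-vocabulary gaps).
    Rows with a pretrained vector copy it verbatim; the rest are sampled
    uniformly in [-r, r] with r = sqrt(3/d).  UNK is the mean of all
    pretrained vectors, or random if there are none.
    """

    def __init__(
        self,
        tokens: List[str],
        matrix: np.ndarray,
        lowercase: bool = True,
    ) -> None:
        self.tokens = tokens
        self.matrix = matrix
        self.lowercase = lowercase
        self._index = {t: i for i, t in enumerate(tokens)}
        self.unk_index = self._index[UNK]
        self.pad_index = self._index[PAD]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def index(self, surface: str) -> int:
        key = surface.lower() if self.lowercase else surface
        return self._index.get(key, self.unk_index)

    @classmethod
    def build(
        cls,
        docs: Iterable[Document],
        dim: int = 100,
        pretrained: Optional[Dict[str, np.ndarray]] = None,
        lowercase: bool = True,
        seed: int = 0,
    ) -> "TokenVocabulary":
        rng = np.random.default_rng(seed)
        norm = (lambda s: s.lower()) if lowercase else (lambda s: s)
        corpus_tokens = sorted({norm(t.surface) for d in docs for t in d.tokens})
        pretrained = pretrained or {}
        if pretrained:
            dim = len(next(iter(pretrained.values())))
        pre_norm: Dict[str, np.ndarray] = {}
        for w, v in pretrained.items():
            pre_norm.setdefault(norm(w), np.asarray(v, dtype=np.float64))
        tokens = list(dict.fromkeys(corpus_tokens + sorted(pre_norm)))
        tokens += [UNK, PAD]
        r = np.sqrt(3.0 / dim)
        matrix = rng.uniform(-r, r, size=(len(tokens), dim))
        for i, tok in enumerate(tokens):
            if tok in pre_norm:
                matrix[i] = pre_norm[tok]
        if pre_norm:
            matrix[-2] = np.mean(np.stack(list(pre_norm.values())), axis=0)
        matrix[-1] = 0.0  # PAD
        return cls(tokens, matrix, lowercase)


class CharVocabulary:
    """Ordered character inventory with UNK/PAD slots; covers every
    character seen in the training tokens (case preserved — the character
    channel is where capitalization information lives)."""

    def __init__(self, chars: List[str]) -> None:
        self.chars = chars
        self._index = {c: i for i, c in enumerate(chars)}
        self.unk_index = len(chars)
        self.pad_index = len(chars) + 1

    @property
    def size(self) -> int:
        return len(self.chars) + 2

    def index(self, ch: str) -> int:
        return self._index.get(ch, self.unk_index)

    @classmethod
    def build(cls, docs: Iterable[Document]) -> "CharVocabulary":
        chars = sorted({c for d in docs for t in d.tokens for c in t.surface})
        return cls(chars)
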