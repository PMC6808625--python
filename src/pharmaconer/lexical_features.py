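"""Per-token lexical feature channels: POS one-hot, gazetteer flag, affix flag.

These are the three signals concatenated onto the character-enhanced token
embedding before the token-level BiLSTM: a one-hot part-of-speech vector, a
boolean dictionary-membership flag (drug names / active ingredients), and a
boolean flag for drug-class affixes such as the local-anesthetic suffix
``-caína``.  All three are raw, untrainable inputs.
"""
from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set

import numpy as np

from .types import FormatError, Token

logger = logging.getLogger(__name__)

AFFIX_KINDS = ("prefix", "suffix", "root")

# Multi-word gazetteer entries are exploded into their component words so a
# per-token lookup can fire on them; fragments shorter than this are noise.
MIN_EXPLODED_WORD_LEN = 3


def normalize(term: str, strip_accents: bool = False) -> str:
    """Lowercase + NFC; accents are lexically meaningful in Spanish and are
    preserved unless explicitly stripped for noisy corpora."""
    term = unicodedata.normalize("NFC", term).lower()
    if strip_accents:
        term = "".join(
            c for c in unicodedata.normalize("NFD", term)
            if unicodedata.category(c) != "Mn"
        )
        term = unicodedata.normalize("NFC", term)
    return term


@dataclass
class Gazetteer:
    terms: Set[str]
    strip_accents: bool = False

    def __contains__(self, surface: str) -> bool:
        return normalize(surface, self.strip_accents) in self.terms


def load_gazetteer(
    path, strip_accents: bool = False, explode_multiword: bool = True
) -> Gazetteer:
    """Load a one-term-per-line dictionary file.

    Blank lines and ``#`` comments are skipped.  Multi-word entries (e.g.
    "ácido acetilsalicílico") are additionally exploded into their component
    words of length >= 3, since the membership check is per token.
    """
    terms: Set[str] = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        term = normalize(line, strip_accents)
        terms.add(term)
        if explode_multiword:
            for word in term.split():
                if len(word) >= MIN_EXPLODED_WORD_LEN:
                    terms.add(word)
    if not terms:
        logger.warning("gazetteer %s is empty; feature will be constant 0", path)
    return Gazetteer(terms, strip_accents)


def gazetteer_feature(token: Token, gazetteer: Optional[Gazetteer]) -> int:
    if gazetteer is None:
        return 0
    return int(token.surface in gazetteer)


@dataclass(frozen=True)
class AffixEntry:
    kind: str  # prefix | suffix | root
    affix_es: str  # Spanish affix with anchoring hyphens stripped
    affix_en: str = ""
    example_en: str = ""
    drug_class: str = ""

    def __post_init__(self) -> None:
        if self.kind not in AFFIX_KINDS:
            raise ValueError(
                f"unknown affix kind {self.kind!r}; accepted: {AFFIX_KINDS}"
            )
        if not self.affix_es:
            raise ValueError("empty Spanish affix")


def load_affixes(path) -> List[AffixEntry]:
    """Load the 5-column affix TSV: type, affix-EN, affix-ES, example-EN,
    drug class.  Only type and the Spanish affix are consumed; the other
    columns are retained for provenance.  A header row is auto-detected.
    """
    entries: List[AffixEntry] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for lineno, raw in enumerate(lines, 1):
        if not raw.strip():
            continue
        cols = raw.split("\t")
        if len(cols) < 5:
            raise FormatError(
                f"{path}:{lineno}: affix rows need 5 tab-separated columns, "
                f"got {len(cols)}"
            )
        kind = cols[0].strip().lower()
        if lineno == 1 and kind not in AFFIX_KINDS:
            continue  # header row
        affix_es = normalize(cols[2].strip().strip("-"))
        try:
            entries.append(
                AffixEntry(kind, affix_es, cols[1].strip(), cols[3].strip(),
                           cols[4].strip())
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    if not entries:
        logger.warning("affix file %s has no entries", path)
    return entries


def affix_match(token: Token, entries: Sequence[AffixEntry]) -> int:
    """1 iff any affix entry matches the token.

    Prefixes anchor at the start, suffixes at the end, roots match anywhere.
    Matching is case-insensitive and accent-sensitive.  A token equal to the
    bare affix counts as a match; tokens shorter than 3 characters never
    match roots (caps false positives on fragments).
    """
    surface = normalize(token.surface)
    for entry in entries:
        if entry.kind == "prefix":
            if surface.startswith(entry.affix_es):
                return 1
        elif entry.kind == "suffix":
            if surface.endswith(entry.affix_es):
                return 1
        else:  # root
            if len(surface) >= MIN_EXPLODED_WORD_LEN and entry.affix_es in surface:
                return 1
    return 0


@dataclass
class PosVocabulary:
    """Frozen ordered POS tag inventory with a trailing UNK slot."""
    tags: List[str]
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.tags)}

    @property
    def dim(self) -> int:
        return len(self.tags) + 1  # + UNK

    def index(self, tag: Optional[str]) -> int:
        if tag is None:
            return len(self.tags)
        return self._index.get(tag, len(self.tags))

    @classmethod
    def from_corpus(cls, docs) -> "PosVocabulary":
        seen = sorted({t.pos for d in docs for t in d.tokens if t.pos is not None})
        return cls(seen)


def pos_onehot(tag: Optional[str], vocab: PosVocabulary) -> np.ndarray:
    vec = np.zeros(vocab.dim, dtype=np.float64)
    vec[vocab.index(tag)] = 1.0
    return vec


@dataclass
class FeatureBundle:
    pos_onehot: np.ndarray
    gazetteer_flag: int
    affix_flag: int


@dataclass
class FeatureExtractor:
    """Bundles the three channels; disabled channels contribute zero width."""
    pos_vocab: Optional[PosVocabulary] = None
    gazetteer: Optional[Gazetteer] = None
    affixes: Optional[Sequence[AffixEntry]] = None

    @property
    def dim(self) -> int:
        d = 0
        if self.pos_vocab is not None:
            d += self.pos_vocab.dim
        if self.gazetteer is not None:
            d += 1
        if self.affixes is not None:
            d += 1
        return d

    def bundle(self, token: Token) -> FeatureBundle:
        return FeatureBundle(
            pos_onehot=(pos_onehot(token.pos, self.pos_vocab)
                        if self.pos_vocab is not None else np.zeros(0)),
            gazetteer_flag=gazetteer_feature(token, self.gazetteer),
            affix_flag=(affix_match(token, self.affixes)
                        if self.affixes is not None else 0),
        )

    def vector(self, token: Token) -> np.ndarray:
        """Concatenated feature vector for enabled channels only."""
        b = self.bundle(token)
        parts = []
        if self.pos_vocab is not None:
            parts.append(b.pos_onehot)
        if self.gazetteer is not None:
            parts.append(np.array([float(b.gazetteer_flag)]))
        if self.affixes is not None:
            parts.append(np.array([float(b.affix_flag)]))
        if not parts:
            return np.zeros(0)
        return np.concatenate(parts)

    def matrix(self, tokens: Iterable[Token]) -> np.ndarray:
        toks = list(tokens)
        if not toks:
            return np.zeros((0, self.dim))
        return np.stack([self.vector(t) for t in toks])
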