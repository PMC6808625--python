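"""Seeded synthetic corpus generator.

Produces BRAT/CoNLL-serializable document collections that emulate the
statistical shape of an annotated Spanish clinical-case corpus: several
entity classes with heavily imbalanced mention counts (default proportions
4398 : 50 : 3009 : 167), entity surfaces correlated with gazetteer
membership and drug-class affixes (``-caína``, ``-cilina``, ``cef-`` ...),
multi-token protein mentions of the ``receptores de X`` shape, and a
class-correlated 10-tag POS inventory.  Surface forms are built from
Spanish-like syllables (accented vowels, ñ) so accent and unicode handling
is genuinely exercised.

Distractors — gazetteer terms occurring in non-entity context — are the
knob that makes the learning problem harder than copying the gazetteer
flag; the ``separability_dial`` presets trivial/easy/hard levels.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .corpus_io import write_brat_dir, write_conll
from .lexical_features import AffixEntry
from .types import Document, Entity, Token

DEFAULT_LABEL_WEIGHTS = {
    "Normalizables": 4398,
    "No_Normalizables": 50,
    "Proteins": 3009,
    "Unclear": 167,
}

POS_TAGS = ("NOUN", "VERB", "ADJ", "ADP", "DET", "PRON",
            "ADV", "NUM", "CONJ", "PUNCT")

DEFAULT_AFFIXES = [
    AffixEntry("suffix", "caína", "-caine", "lidocaine", "local anesthetic"),
    AffixEntry("suffix", "cilina", "-cillin", "amoxicillin", "antibiotic"),
    AffixEntry("suffix", "micina", "-mycin", "erythromycin", "antibiotic"),
    AffixEntry("suffix", "olol", "-olol", "propranolol", "beta blocker"),
    AffixEntry("prefix", "cef", "cef-", "cefazolin", "cephalosporin"),
    AffixEntry("root", "tiaz", "-thiaz-", "hydrochlorothiazide", "diuretic"),
]

_ONSETS = ["b", "c", "d", "f", "g", "l", "m", "n", "ñ", "p", "r", "s",
           "t", "v", "br", "tr", "gl", "pl"]
_VOWELS = ["a", "e", "i", "o", "u", "a", "e", "o", "á", "é", "í", "ó", "ú"]
_CODAS = ["", "", "", "n", "s", "r", "l"]


@dataclass
class CorpusSpec:
    """Generation parameters; defaults give the desk-scale CI corpus
    (200 documents of ~15 sentences) with the default class imbalance."""
    n_docs: int = 200
    sentences_per_doc_mean: float = 15.0
    sentences_per_doc_sd: float = 4.0
    sentence_len_mean: float = 9.0
    sentence_len_sd: float = 3.0
    label_weights: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_WEIGHTS))
    entity_rate: float = 0.7  # probability a sentence carries a mention
    gazetteer_fraction: float = 0.7  # mentions drawn from the gazetteer
    affix_fraction: float = 0.2  # mentions carrying a drug-class affix
    multi_token_fraction: float = 0.3  # of gazetteer protein mentions
    distractor_rate: float = 0.05  # sentences with an unannotated gaz term
    background_vocab: int = 300
    entity_vocab_per_label: int = 120
    gazetteer_per_label: int = 120
    comma_rate: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("entity_rate", "gazetteer_fraction", "affix_fraction",
                     "multi_token_fraction", "distractor_rate", "comma_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.gazetteer_fraction + self.affix_fraction > 1.0 + 1e-9:
            raise ValueError("gazetteer + affix fractions exceed 1")
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")


def separability_dial(spec: CorpusSpec, level: str) -> CorpusSpec:
    """Preset difficulty levels.

    trivial: entities are exactly the gazetteer hits — a dictionary rule is
    Bayes-optimal (F1 100), used to ceiling-check the model.
    easy: 90% of mentions carry a cue, 5% of sentences contain a distractor.
    hard: 50% cue-bearing mentions, 20% distractor sentences.
    """
    presets = {
        "trivial": dict(gazetteer_fraction=1.0, affix_fraction=0.0,
                        distractor_rate=0.0, multi_token_fraction=0.0),
        "easy": dict(gazetteer_fraction=0.7, affix_fraction=0.2,
                     distractor_rate=0.05, multi_token_fraction=0.3),
        "hard": dict(gazetteer_fraction=0.35, affix_fraction=0.15,
                     distractor_rate=0.20, multi_token_fraction=0.3),
    }
    if level not in presets:
        raise ValueError(f"level must be one of {sorted(presets)}")
    return replace(spec, **presets[level])


@dataclass
class Lexicon:
    """Per-label surface pools plus the shared background vocabulary."""
    background: List[str]
    gazetteer: Dict[str, List[str]]  # label -> gazetteer terms (may be multiword)
    affixed: Dict[str, List[str]]    # label -> affix-bearing, non-gazetteer
    plain: Dict[str, List[str]]      # label -> cue-free entity words
    affix_entries: List[AffixEntry]

    @property
    def gazetteer_terms(self) -> Set[str]:
        return {t for terms in self.gazetteer.values() for t in terms}

    @property
    def term_labels(self) -> Dict[str, str]:
        """term -> label map for the dictionary-rule baseline."""
        return {t: lab for lab, terms in self.gazetteer.items() for t in terms}


@dataclass
class GeneratedCorpus:
    docs: List[Document]
    lexicon: Lexicon
    spec: CorpusSpec

    @property
    def gazetteer_lines(self) -> List[str]:
        return sorted(self.lexicon.gazetteer_terms)

    @property
    def affix_lines(self) -> List[str]:
        rows = ["type\taffix_en\taffix_es\texample_en\tdrug_class"]
        for e in self.lexicon.affix_entries:
            es = {"prefix": e.affix_es + "-",
                  "suffix": "-" + e.affix_es,
                  "root": "-" + e.affix_es + "-"}[e.kind]
            rows.append(f"{e.kind}\t{e.affix_en}\t{es}\t{e.example_en}"
                        f"\t{e.drug_class}")
        return rows

    def write(self, directory) -> None:
        """Emit brat/, conll/, gazetteer.txt, affixes.tsv and spec.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_brat_dir(self.docs, directory / "brat")
        (directory / "conll").mkdir(exist_ok=True)
        write_conll(self.docs, directory / "conll" / "corpus.conll")
        (directory / "gazetteer.txt").write_text(
            "".join(t + "\n" for t in self.gazetteer_lines), encoding="utf-8")
        (directory / "affixes.tsv").write_text(
            "".join(r + "\n" for r in self.affix_lines), encoding="utf-8")
        (directory / "spec.json").write_text(
            json.dumps(asdict(self.spec), indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# Surface-form machinery
# ---------------------------------------------------------------------------

def _syllable(rng: np.random.Generator) -> str:
    return (str(rng.choice(_ONSETS)) + str(rng.choice(_VOWELS))
            + str(rng.choice(_CODAS)))


def _word(rng: np.random.Generator, n_syllables: Optional[int] = None) -> str:
    n = n_syllables or int(rng.integers(2, 5))
    return "".join(_syllable(rng) for _ in range(n))


def _fresh_words(rng, n: int, taken: Set[str], forbidden: Sequence[str],
                 with_affix: Optional[AffixEntry] = None) -> List[str]:
    """Generate n unique words; without ``with_affix`` the words contain no
    affix substring at an anchored position, with it they carry exactly it."""
    out: List[str] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 200 * n + 1000:
            raise RuntimeError("cannot generate enough distinct words")
        if with_affix is None:
            w = _word(rng)
            if _has_any_affix(w, forbidden):
                continue
        else:
            stem = _word(rng, 2)
            if _has_any_affix(stem, forbidden):
                continue
            if with_affix.kind == "prefix":
                w = with_affix.affix_es + stem
            elif with_affix.kind == "suffix":
                w = stem + with_affix.affix_es
            else:
                w = stem + with_affix.affix_es + _syllable(rng)
        if w in taken:
            continue
        taken.add(w)
        out.append(w)
    return out


def _has_any_affix(word: str, affixes: Sequence) -> bool:
    for a in affixes:
        s = a.affix_es if isinstance(a, AffixEntry) else a
        if s in word:
            return True
    return False


def build_lexicon(spec: CorpusSpec, rng: np.random.Generator) -> Lexicon:
    affixes = list(DEFAULT_AFFIXES)
    taken: Set[str] = set()
    background = _fresh_words(rng, spec.background_vocab, taken, affixes)
    gazetteer: Dict[str, List[str]] = {}
    affixed: Dict[str, List[str]] = {}
    plain: Dict[str, List[str]] = {}
    drug_labels = {"Normalizables", "No_Normalizables"}
    for label in spec.label_weights:
        n_gaz = spec.gazetteer_per_label
        if label in drug_labels:
            # half the dictionary terms also carry an affix, as real
            # nomenclator entries do
            with_affix = [
                _fresh_words(rng, 1, taken, [],
                             with_affix=affixes[int(rng.integers(len(affixes)))])[0]
                for _ in range(n_gaz // 2)
            ]
            without = _fresh_words(rng, n_gaz - len(with_affix), taken, affixes)
            gazetteer[label] = with_affix + without
        elif label == "Proteins":
            singles = _fresh_words(rng, n_gaz, taken, affixes)
            multi = [f"receptores de {w}"
                     for w in _fresh_words(rng, n_gaz // 2, taken, affixes)]
            gazetteer[label] = singles + multi
        else:
            gazetteer[label] = _fresh_words(rng, n_gaz, taken, affixes)
        affix_pool = []
        for _ in range(spec.entity_vocab_per_label):
            entry = affixes[int(rng.integers(len(affixes)))]
            affix_pool.extend(_fresh_words(rng, 1, taken, [], with_affix=entry))
        affixed[label] = affix_pool
        plain[label] = _fresh_words(rng, spec.entity_vocab_per_label, taken,
                                    affixes)
    return Lexicon(background, gazetteer, affixed, plain, affixes)


# ---------------------------------------------------------------------------
# Corpus assembly
# ---------------------------------------------------------------------------

def _allocate_labels(weights: Dict[str, int], n: int,
                     rng: np.random.Generator) -> List[str]:
    """Largest-remainder proportional allocation of n mention slots, then a
    seeded shuffle — realized class counts track the target ratios to ±1."""
    labels = sorted(weights)
    total = sum(weights[lab] for lab in labels)
    raw = {lab: n * weights[lab] / total for lab in labels}
    counts = {lab: int(np.floor(raw[lab])) for lab in labels}
    short = n - sum(counts.values())
    for lab in sorted(labels, key=lambda l: raw[l] - counts[l], reverse=True):
        if short <= 0:
            break
        counts[lab] += 1
        short -= 1
    out = [lab for lab in labels for _ in range(counts[lab])]
    rng.shuffle(out)
    return out


class _DocBuilder:
    def __init__(self, doc_id: str) -> None:
        self.doc_id = doc_id
        self.text: List[str] = []
        self.pos = 0
        self.tokens: List[Token] = []
        self.entities: List[Entity] = []

    def add(self, surface: str, pos_tag: str, glue: bool = False) -> Token:
        if self.tokens and not glue:
            self.text.append(" ")
            self.pos += 1
        tok = Token(surface, self.pos, self.pos + len(surface), pos_tag)
        self.text.append(surface)
        self.pos += len(surface)
        self.tokens.append(tok)
        return tok

    def finish(self) -> Document:
        doc = Document(self.doc_id, "".join(self.text), self.tokens,
                       sorted(self.entities, key=lambda e: e.start))
        doc.validate()
        return doc


def _entity_surface(label: str, route: str, lexicon: Lexicon,
                    spec: CorpusSpec, rng: np.random.Generator) -> str:
    if route == "gazetteer":
        terms = lexicon.gazetteer[label]
        if label == "Proteins":
            multi = [t for t in terms if " " in t]
            single = [t for t in terms if " " not in t]
            if multi and rng.random() < spec.multi_token_fraction:
                return str(multi[int(rng.integers(len(multi)))])
            terms = single
        return str(terms[int(rng.integers(len(terms)))])
    pool = lexicon.affixed[label] if route == "affix" else lexicon.plain[label]
    return str(pool[int(rng.integers(len(pool)))])


def generate(spec: CorpusSpec, out_dir=None) -> GeneratedCorpus:
    """Generate a corpus (and optionally write it to ``out_dir``).

    Deterministic under ``spec.seed``: the same spec yields byte-identical
    BRAT and CoNLL output across runs.
    """
    rng = np.random.default_rng(spec.seed)
    lexicon = build_lexicon(spec, rng)

    # plan sentence counts/lengths and mention slots first so labels can be
    # allocated exactly proportionally over the whole corpus
    plan: List[List[Tuple[int, bool]]] = []
    n_slots = 0
    for _ in range(spec.n_docs):
        n_sent = max(1, int(round(rng.normal(spec.sentences_per_doc_mean,
                                             spec.sentences_per_doc_sd))))
        sentences = []
        for _ in range(n_sent):
            length = max(4, int(round(rng.normal(spec.sentence_len_mean,
                                                 spec.sentence_len_sd))))
            has_entity = bool(rng.random() < spec.entity_rate)
            n_slots += has_entity
            sentences.append((length, has_entity))
        plan.append(sentences)
    slot_labels = _allocate_labels(spec.label_weights, n_slots, rng)

    docs: List[Document] = []
    slot_i = 0
    for d, sentences in enumerate(plan):
        builder = _DocBuilder(f"synth{d:04d}")
        for length, has_entity in sentences:
            entity_pos = int(rng.integers(1, length)) if has_entity else -1
            distractor_pos = -1
            if spec.distractor_rate and rng.random() < spec.distractor_rate:
                distractor_pos = int(rng.integers(1, length))
                if distractor_pos == entity_pos:
                    distractor_pos = -1
            first_in_sentence = True
            for i in range(length):
                if i == entity_pos:
                    label = slot_labels[slot_i]
                    slot_i += 1
                    u = rng.random()
                    if u < spec.gazetteer_fraction:
                        route = "gazetteer"
                    elif u < spec.gazetteer_fraction + spec.affix_fraction:
                        route = "affix"
                    else:
                        route = "plain"
                    surface = _entity_surface(label, route, lexicon, spec, rng)
                    words = surface.split(" ")
                    start_tok = None
                    for w in words:
                        pos_tag = "ADP" if w == "de" else "NOUN"
                        tok = builder.add(w, pos_tag)
                        if start_tok is None:
                            start_tok = tok
                    builder.entities.append(Entity(
                        label, start_tok.start, builder.tokens[-1].end,
                        " ".join(words)))
                elif i == distractor_pos:
                    terms = [t for t in lexicon.gazetteer_terms if " " not in t]
                    builder.add(str(sorted(terms)[int(rng.integers(len(terms)))]),
                                "NOUN")
                else:
                    w = lexicon.background[int(rng.integers(len(lexicon.background)))]
                    if first_in_sentence:
                        w = w[0].upper() + w[1:]
                    pos_tag = str(rng.choice(
                        ["NOUN", "VERB", "ADJ", "ADP", "DET", "PRON", "ADV",
                         "CONJ"],
                        p=[0.3, 0.2, 0.15, 0.1, 0.1, 0.05, 0.05, 0.05]))
                    builder.add(w, pos_tag)
                    if (spec.comma_rate and i < length - 1
                            and rng.random() < spec.comma_rate):
                        builder.add(",", "PUNCT", glue=True)
                first_in_sentence = False
            builder.add(".", "PUNCT", glue=True)
        docs.append(builder.finish())

    corpus = GeneratedCorpus(docs, lexicon, spec)
    if out_dir is not None:
        corpus.write(out_dir)
    return corpus


def dictionary_baseline(
    docs: Sequence[Document], term_labels: Dict[str, str]
) -> List[Document]:
    """The "tag gazetteer hits as entities" rule: every token (or
    ``receptores de X`` trigram) whose normalized surface is a dictionary
    term becomes an entity with the term's label.  Bayes-optimal on the
    trivial separability level, increasingly wrong as distractors and
    cue-free mentions appear."""
    from .lexical_features import normalize
    norm_terms = {normalize(t): lab for t, lab in term_labels.items()}
    out = []
    for doc in docs:
        entities = []
        i = 0
        toks = doc.tokens
        while i < len(toks):
            tri = " ".join(t.surface for t in toks[i:i + 3])
            if i + 2 < len(toks) and normalize(tri) in norm_terms:
                entities.append(Entity(norm_terms[normalize(tri)],
                                       toks[i].start, toks[i + 2].end,
                                       doc.text[toks[i].start:toks[i + 2].end]))
                i += 3
                continue
            surf = normalize(toks[i].surface)
            if surf in norm_terms:
                entities.append(Entity(norm_terms[surf], toks[i].start,
                                       toks[i].end, toks[i].surface))
            i += 1
        out.append(Document(doc.doc_id, doc.text, list(doc.tokens), entities))
    return out
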