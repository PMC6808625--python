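"""BRAT standoff and CoNLL reading/writing, tokenization, tag conversion.

The CoNLL dialect used here is token-per-line with columns

    surface  doc_id  start  end  [pos]  gold_tag  [pred_tag]

(5, 6 or 7 whitespace-separated columns; a ``_`` POS cell means "no tag"),
blank lines as sentence separators and optional ``-DOCSTART-`` lines that
are ignored.  BRAT files are the usual ``.txt`` + ``.ann`` pair with
text-bound annotations ``T<k><TAB><label> <start> <end><TAB><surface>``;
discontinuous spans are rejected.
"""
from __future__ import annotations

import logging
import re
import unicodedata
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .types import (
    BIO,
    BIOES,
    AlignmentError,
    Document,
    Entity,
    FormatError,
    TagSequence,
    Token,
    _split_tag,
)

logger = logging.getLogger(__name__)

__all__ = [
    "tokenize",
    "read_brat",
    "write_brat",
    "read_conll",
    "write_conll",
    "entities_to_tags",
    "bio_to_entities",
    "sentence_spans",
]


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch)[0] in ("P", "S")


def _keep_attached(chunk: str, i: int) -> bool:
    """Intra-word hyphens and decimal separators stay inside the token."""
    ch = chunk[i]
    if i == 0 or i == len(chunk) - 1:
        return False
    prev, nxt = chunk[i - 1], chunk[i + 1]
    if ch == "-":
        return prev.isalnum() and nxt.isalnum()
    if ch in (",", "."):
        return prev.isdigit() and nxt.isdigit()
    return False


def tokenize(text: str) -> List[Token]:
    """Rule-based tokenizer with character offsets.

    Splits on unicode whitespace, then isolates punctuation and symbol
    characters as single-character tokens, keeping intra-word hyphens
    (``anti-TNF``) and decimal commas/dots (``0,5``) attached — the
    punctuation-heavy conventions of Spanish clinical notes make these
    rules worth being explicit about.
    """
    tokens: List[Token] = []
    for m in re.finditer(r"\S+", text):
        chunk, base = m.group(), m.start()
        run_start = 0  # start of the in-progress word piece, chunk-relative
        for i, ch in enumerate(chunk):
            if _is_punct(ch) and not _keep_attached(chunk, i):
                if i > run_start:
                    tokens.append(
                        Token(chunk[run_start:i], base + run_start, base + i)
                    )
                tokens.append(Token(ch, base + i, base + i + 1))
                run_start = i + 1
        if run_start < len(chunk):
            tokens.append(
                Token(chunk[run_start:], base + run_start, base + len(chunk))
            )
    return tokens


# ---------------------------------------------------------------------------
# Entity spans <-> tag sequences
# ---------------------------------------------------------------------------

def entities_to_tags(
    doc: Document,
    scheme: str = BIOES,
    expand_boundaries: bool = False,
) -> TagSequence:
    """Project entity spans onto per-token BIO/BIOES tags.

    Entity boundaries must coincide with token boundaries; with
    ``expand_boundaries`` a misaligned boundary is snapped outward to the
    enclosing token (logged per entity) instead of raising.
    Overlapping entities are always an error (no nesting support).
    """
    tags = ["O"] * len(doc.tokens)
    starts = {t.start: i for i, t in enumerate(doc.tokens)}
    ends = {t.end: i for i, t in enumerate(doc.tokens)}
    claimed = [False] * len(doc.tokens)
    for ent in sorted(doc.entities, key=lambda e: (e.start, e.end)):
        first = starts.get(ent.start)
        last = ends.get(ent.end)
        if first is None or last is None:
            if not expand_boundaries:
                raise AlignmentError(
                    f"entity ({ent.label},{ent.start},{ent.end},{ent.surface!r}) "
                    "does not align with token boundaries"
                )
            first = next(
                (i for i, t in enumerate(doc.tokens) if t.end > ent.start), None
            )
            last = next(
                (i for i in range(len(doc.tokens) - 1, -1, -1)
                 if doc.tokens[i].start < ent.end),
                None,
            )
            if first is None or last is None or first > last:
                raise AlignmentError(
                    f"entity ({ent.label},{ent.start},{ent.end}) covers no token"
                )
            logger.warning(
                "expanded entity (%s,%d,%d) to token span %d..%d",
                ent.label, ent.start, ent.end, first, last,
            )
        if any(claimed[first:last + 1]):
            raise AlignmentError(
                f"overlapping entities at tokens {first}..{last} "
                f"({ent.label},{ent.start},{ent.end})"
            )
        for i in range(first, last + 1):
            claimed[i] = True
        if scheme == BIO:
            tags[first] = f"B-{ent.label}"
            for i in range(first + 1, last + 1):
                tags[i] = f"I-{ent.label}"
        else:
            if first == last:
                tags[first] = f"S-{ent.label}"
            else:
                tags[first] = f"B-{ent.label}"
                for i in range(first + 1, last):
                    tags[i] = f"I-{ent.label}"
                tags[last] = f"E-{ent.label}"
    return TagSequence(scheme, tags)


def repair_tags(tags: Sequence[str], scheme: str) -> List[str]:
    """Make a tag sequence scheme-valid: a stray I-X (or E-X) becomes B-X.

    Standard CoNLL reading practice; keeps the span decoder total.
    """
    fixed: List[str] = []
    open_label = None
    for tag in tags:
        try:
            prefix, label = _split_tag(tag)
        except ValueError:
            prefix, label = "O", None
            tag = "O"
        if prefix in ("I", "E") and label != open_label:
            tag = f"B-{label}" if (scheme == BIO or prefix == "I") else f"S-{label}"
            prefix = tag[0]
        if prefix in ("B", "I"):
            open_label = label
        else:
            open_label = None
        fixed.append(tag)
    return fixed


def bio_to_entities(
    tokens: Sequence[Token], tag_seq: TagSequence, text: Optional[str] = None
) -> List[Entity]:
    """Decode per-token tags back to character-offset entity spans.

    Inverse of :func:`entities_to_tags` on valid sequences; malformed
    sequences are repaired first (stray continuation tags start a new
    entity), so decoding never fails.
    """
    if len(tag_seq.tags) != len(tokens):
        raise ValueError(
            f"{len(tag_seq.tags)} tags for {len(tokens)} tokens"
        )
    tags = repair_tags(tag_seq.tags, tag_seq.scheme)
    entities: List[Entity] = []
    span_start = None
    span_label = None

    def flush(last_index: int) -> None:
        nonlocal span_start, span_label
        if span_label is None:
            return
        start = tokens[span_start].start
        end = tokens[last_index].end
        surface = (
            text[start:end] if text is not None
            else _join_surfaces(tokens[span_start:last_index + 1])
        )
        entities.append(Entity(span_label, start, end, surface))
        span_start = span_label = None

    for i, tag in enumerate(tags):
        prefix, label = _split_tag(tag)
        if prefix in ("B", "S") or (prefix in ("I", "E") and label != span_label):
            flush(i - 1)
            span_start, span_label = i, label
        if prefix in ("E", "S"):
            flush(i)
        elif prefix == "O":
            flush(i - 1)
    flush(len(tags) - 1)
    return entities


def _join_surfaces(tokens: Sequence[Token]) -> str:
    parts = [tokens[0].surface]
    for prev, tok in zip(tokens, tokens[1:]):
        parts.append(" " * (tok.start - prev.end))
        parts.append(tok.surface)
    return "".join(parts)


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

_SENT_FINAL = {".", "?", "!"}


def sentence_spans(doc: Document) -> List[Tuple[int, int]]:
    """Token-index ranges [i, j) of sentences.

    Breaks after sentence-final ``. ? !`` when followed by whitespace and
    an uppercase letter; the document remains the unit of annotation.
    """
    spans: List[Tuple[int, int]] = []
    start = 0
    for i, tok in enumerate(doc.tokens[:-1]):
        nxt = doc.tokens[i + 1]
        if (
            tok.surface in _SENT_FINAL
            and nxt.start > tok.end
            and nxt.surface[0].isupper()
        ):
            spans.append((start, i + 1))
            start = i + 1
    if start < len(doc.tokens):
        spans.append((start, len(doc.tokens)))
    return spans


# ---------------------------------------------------------------------------
# BRAT standoff
# ---------------------------------------------------------------------------

def read_brat(
    txt_path, ann_path, tokenize_text: bool = True, lenient: bool = False
) -> Document:
    """Read a ``.txt`` + ``.ann`` BRAT pair into a Document.

    Only text-bound (``T``) annotations are consumed; notes and relations
    are ignored.  Offsets are checked against the text and the stored
    surface; a mismatch is a :class:`FormatError` unless ``lenient``, in
    which case it is logged and the text's own slice wins.
    """
    txt_path, ann_path = Path(txt_path), Path(ann_path)
    text = txt_path.read_text(encoding="utf-8")
    entities: List[Entity] = []
    for lineno, line in enumerate(
        ann_path.read_text(encoding="utf-8").splitlines(), 1
    ):
        if not line.strip() or not line.startswith("T"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{ann_path}:{lineno}: text-bound annotation needs 3 "
                f"tab-separated fields, got {len(parts)}"
            )
        ann_id, span_expr, surface = parts[0], parts[1], parts[2]
        if ";" in span_expr:
            raise FormatError(
                f"{ann_path}:{lineno}: discontinuous span in {ann_id} "
                "is not supported"
            )
        try:
            label, start_s, end_s = span_expr.rsplit(" ", 2)
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(
                f"{ann_path}:{lineno}: cannot parse span {span_expr!r}"
            ) from None
        if start < 0 or end > len(text) or end <= start:
            raise FormatError(
                f"{ann_path}:{lineno}: {ann_id} offsets ({start},{end}) "
                f"outside text of length {len(text)}"
            )
        actual = text[start:end]
        if actual != surface:
            if not lenient:
                raise FormatError(
                    f"{ann_path}:{lineno}: {ann_id} surface {surface!r} != "
                    f"text slice {actual!r}"
                )
            logger.warning(
                "%s:%d: %s surface mismatch, using text slice",
                ann_path, lineno, ann_id,
            )
            surface = actual
        entities.append(Entity(label, start, end, surface))
    doc = Document(
        doc_id=txt_path.stem,
        text=text,
        tokens=tokenize(text) if tokenize_text else [],
        entities=sorted(entities, key=lambda e: (e.start, e.end)),
    )
    doc.validate()
    return doc


def write_brat(doc: Document, txt_path, ann_path) -> None:
    Path(txt_path).write_text(doc.text, encoding="utf-8")
    lines = [
        f"T{i}\t{e.label} {e.start} {e.end}\t{e.surface}"
        for i, e in enumerate(
            sorted(doc.entities, key=lambda e: (e.start, e.end)), 1
        )
    ]
    Path(ann_path).write_text(
        "".join(line + "\n" for line in lines), encoding="utf-8"
    )


def read_brat_dir(directory, lenient: bool = False) -> List[Document]:
    """Read every ``.txt``/``.ann`` pair in a directory, sorted by name."""
    directory = Path(directory)
    docs = []
    for txt in sorted(directory.glob("*.txt")):
        ann = txt.with_suffix(".ann")
        if not ann.exists():
            raise FormatError(f"missing annotation file {ann}")
        docs.append(read_brat(txt, ann, lenient=lenient))
    return docs


def write_brat_dir(docs: Iterable[Document], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        write_brat(doc, directory / f"{doc.doc_id}.txt",
                   directory / f"{doc.doc_id}.ann")


# ---------------------------------------------------------------------------
# CoNLL
# ---------------------------------------------------------------------------

def write_conll(
    docs: Iterable[Document],
    path,
    scheme: str = BIOES,
    predicted: Optional[Dict[str, TagSequence]] = None,
) -> None:
    """Write documents token-per-line; see the module docstring for columns.

    ``predicted`` optionally maps doc_id to a predicted tag sequence,
    emitted as a trailing column (the conlleval convention of gold before
    predicted).
    """
    lines: List[str] = []
    for doc in docs:
        gold = entities_to_tags(doc, scheme)
        pred = predicted.get(doc.doc_id) if predicted else None
        if pred is not None and len(pred.tags) != len(doc.tokens):
            raise ValueError(f"{doc.doc_id}: predicted tag length mismatch")
        for si, (lo, hi) in enumerate(sentence_spans(doc)):
            for i in range(lo, hi):
                tok = doc.tokens[i]
                cols = [tok.surface, doc.doc_id, str(tok.start), str(tok.end),
                        tok.pos if tok.pos is not None else "_",
                        gold.tags[i]]
                if pred is not None:
                    cols.append(pred.tags[i])
                lines.append(" ".join(cols))
            lines.append("")
    Path(path).write_text(
        "".join(line + "\n" for line in lines), encoding="utf-8"
    )


def read_conll(path, scheme: Optional[str] = None) -> List[Document]:
    """Read a CoNLL file back into documents (see module docstring).

    The tagging scheme is auto-detected from tag prefixes unless given.
    Documents are reassembled by the doc_id column; the raw text is
    reconstructed by placing tokens at their stored offsets with spaces
    in the gaps.
    """
    path = Path(path)
    rows: Dict[str, list] = {}
    order: List[str] = []
    has_pred = None
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), 1
    ):
        if not line.strip():
            continue
        if line.startswith("-DOCSTART-"):
            continue
        cols = line.split()
        if len(cols) not in (5, 6, 7):
            raise FormatError(
                f"{path}:{lineno}: expected 5-7 columns, got {len(cols)}"
            )
        if has_pred is None:
            has_pred = len(cols) == 7
        elif has_pred != (len(cols) == 7):
            raise FormatError(f"{path}:{lineno}: ragged column count")
        if len(cols) == 5:  # pos column absent entirely
            surface, doc_id, start_s, end_s = cols[:4]
            pos = "_"
            cols = cols[:4] + ["_", cols[4]]
        else:
            surface, doc_id, start_s, end_s, pos = cols[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: bad offsets {start_s!r} {end_s!r}"
            ) from None
        if doc_id not in rows:
            rows[doc_id] = []
            order.append(doc_id)
        rows[doc_id].append(
            (Token(surface, start, end, None if pos == "_" else pos),
             cols[5], cols[6] if has_pred else None)
        )
    docs: List[Document] = []
    for doc_id in order:
        toks = [r[0] for r in rows[doc_id]]
        tags = [r[1] for r in rows[doc_id]]
        sch = scheme or _detect_scheme(tags)
        text = _reconstruct_text(toks)
        entities = bio_to_entities(toks, TagSequence(sch, tags), text)
        doc = Document(doc_id, text, toks, entities)
        doc.validate()
        docs.append(doc)
    return docs


def read_conll_tag_columns(path) -> List[Tuple[List[str], List[str]]]:
    """Per-document (gold, predicted) tag column pairs from a 7-column file."""
    path = Path(path)
    pairs: Dict[str, Tuple[List[str], List[str]]] = {}
    order = []
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), 1
    ):
        if not line.strip() or line.startswith("-DOCSTART-"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise FormatError(
                f"{path}:{lineno}: expected 7 columns (gold+predicted), "
                f"got {len(cols)}"
            )
        doc_id = cols[1]
        if doc_id not in pairs:
            pairs[doc_id] = ([], [])
            order.append(doc_id)
        pairs[doc_id][0].append(cols[5])
        pairs[doc_id][1].append(cols[6])
    return [pairs[d] for d in order]


def _detect_scheme(tags: Sequence[str]) -> str:
    return BIOES if any(t[:2] in ("S-", "E-") for t in tags) else BIO


def _reconstruct_text(tokens: Sequence[Token]) -> str:
    if not tokens:
        return ""
    out = []
    pos = 0
    for tok in tokens:
        if tok.start < pos:
            raise FormatError(
                f"token offsets overlap at {tok.start} (surface {tok.surface!r})"
            )
        out.append(" " * (tok.start - pos))
        out.append(tok.surface)
        pos = tok.end
    return "".join(out)
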