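"""Core domain types: tokens, entities, documents and tag sequences.

Offsets are 0-based, end-exclusive character offsets into the owning
document's raw text (the BRAT convention); newlines count as characters.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

BIO = "BIO"
BIOES = "BIOES"
SCHEMES = (BIO, BIOES)


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


class AlignmentError(ValueError):
    """Raised when entity boundaries do not align with token boundaries."""


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    pos: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"token end {self.end} <= start {self.start}")
        if not self.surface:
            raise ValueError("empty token surface")
        if "\n" in self.surface:
            raise ValueError("token surface contains newline")


@dataclass(frozen=True)
class Entity:
    label: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"entity end {self.end} <= start {self.start}")


@dataclass
class Document:
    doc_id: str
    text: str
    tokens: List[Token] = field(default_factory=list)
    entities: List[Entity] = field(default_factory=list)

    def validate(self) -> None:
        """Check the documented invariants; raise ValueError on violation."""
        prev_end = -1
        for tok in self.tokens:
            if tok.start < prev_end:
                raise ValueError(
                    f"{self.doc_id}: token offsets not increasing at {tok.start}"
                )
            if self.text[tok.start:tok.end] != tok.surface:
                raise ValueError(
                    f"{self.doc_id}: token surface {tok.surface!r} != "
                    f"text[{tok.start}:{tok.end}]"
                )
            prev_end = tok.end
        for ent in self.entities:
            if ent.start < 0 or ent.end > len(self.text):
                raise ValueError(
                    f"{self.doc_id}: entity ({ent.label},{ent.start},{ent.end}) "
                    "outside text"
                )
            if self.text[ent.start:ent.end] != ent.surface:
                raise ValueError(
                    f"{self.doc_id}: entity surface {ent.surface!r} != "
                    f"text[{ent.start}:{ent.end}]"
                )


@dataclass
class TagSequence:
    scheme: str
    tags: List[str]

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def is_valid(self) -> bool:
        """True iff the tags obey the scheme grammar."""
        return _scheme_valid(self.tags, self.scheme)


def _split_tag(tag: str):
    if tag == "O":
        return "O", None
    if len(tag) > 2 and tag[1] == "-":
        return tag[0], tag[2:]
    raise ValueError(f"malformed tag {tag!r}")


def _scheme_valid(tags: Sequence[str], scheme: str) -> bool:
    open_label = None  # label of an entity still expecting continuation
    for tag in tags:
        try:
            prefix, label = _split_tag(tag)
        except ValueError:
            return False
        if scheme == BIO:
            if prefix not in ("O", "B", "I"):
                return False
            if prefix == "I" and label != open_label:
                return False
            open_label = label if prefix in ("B", "I") else None
        else:  # BIOES
            if prefix not in ("O", "B", "I", "E", "S"):
                return False
            if prefix in ("I", "E"):
                if label != open_label:
                    return False
                open_label = label if prefix == "I" else None
            elif prefix == "B":
                if open_label is not None:
                    return False
                open_label = label
            else:  # O or S
                if open_label is not None:
                    return False
    return open_label is None if scheme == BIOES else True
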