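"""Dependency distance as a formal syntactic-complexity index.

A dependency arc links a token to its head; its distance is the absolute
difference of the two 1-based linear positions in the sentence.  In
"Mary ate the juicy red sweet apple", *apple* (position 7) depends on
*ate* (position 2), giving distance 5.  The averaged dependency distance
(ADD) pools every arc across every sentence of a transcript; longer
arcs indicate a deeper, more demanding syntactic hierarchy.

Arcs touching punctuation are skipped, but the remaining tokens keep
their original positions — distances always count through intervening
words.  An alternative "words in between" convention (distance 4 for the
ate-apple arc) is available via ``convention="gap"`` but is not the
default.

Parses are exchanged in CoNLL-U layout (10 tab-separated columns; this
module uses ID, FORM, UPOS, HEAD, DEPREL and flags punctuation by
``UPOS == "PUNCT"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ParseToken",
    "DependencyParse",
    "arc_distances",
    "averaged_dependency_distance",
    "read_conllu",
    "write_conllu",
]

ROOT = 0  # head index marking the sentence root


@dataclass(frozen=True)
class ParseToken:
    form: str
    position: int  # 1-based linear position
    head: int  # 1-based head position, or ROOT (0)
    is_punct: bool = False
    deprel: str = "dep"


@dataclass(frozen=True)
class DependencyParse:
    """One sentence's dependency tree.

    Exactly one token is the root; every head reference must name an
    existing token and no token may head itself.
    """

    tokens: tuple[ParseToken, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        positions = [t.position for t in self.tokens]
        if positions != list(range(1, len(self.tokens) + 1)):
            raise ValueError("token positions must be 1..n in order")
        roots = [t for t in self.tokens if t.head == ROOT]
        if self.tokens and len(roots) != 1:
            raise ValueError(f"parse must have exactly one root, found {len(roots)}")
        valid = set(positions)
        for t in self.tokens:
            if t.head != ROOT and t.head not in valid:
                raise ValueError(f"token {t.position} has dangling head {t.head}")
            if t.head == t.position:
                raise ValueError(f"token {t.position} heads itself")

    def __len__(self) -> int:
        return len(self.tokens)


def arc_distances(parse: DependencyParse, convention: str = "absolute") -> list[int]:
    """Distances of all non-punctuation dependency arcs.

    For every non-root token, emit ``|position(token) - position(head)|``
    on the original linear positions, skipping arcs where either end is
    punctuation.  ``convention="gap"`` instead counts the words strictly
    in between (absolute distance minus one).
    """
    if convention not in ("absolute", "gap"):
        raise ValueError(f"unknown convention {convention!r}")
    by_pos = {t.position: t for t in parse.tokens}
    offset = 1 if convention == "gap" else 0
    return [
        abs(t.position - t.head) - offset
        for t in parse.tokens
        if t.head != ROOT and not t.is_punct and not by_pos[t.head].is_punct
    ]


def averaged_dependency_distance(
    parses: Sequence[DependencyParse], convention: str = "absolute"
) -> float:
    """Mean arc distance pooled across all sentences; NaN with zero arcs."""
    if not parses:
        raise ValueError("averaged_dependency_distance requires at least one parse")
    pooled = [d for p in parses for d in arc_distances(p, convention)]
    if not pooled:
        return math.nan
    return float(sum(pooled) / len(pooled))


# ---------------------------------------------------------------------------
# CoNLL-U I/O (columns: ID FORM LEMMA UPOS XPOS FEATS HEAD DEPREL DEPS MISC)


def read_conllu(source: str | Path) -> list[DependencyParse]:
    """Read sentences from CoNLL-U text or a file path.

    Multiword-token ranges (``1-2``) and empty nodes (``1.1``) are
    skipped; punctuation is flagged by ``UPOS == "PUNCT"``.
    """
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) else source
    sentences: list[DependencyParse] = []
    current: list[ParseToken] = []
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            if current:
                sentences.append(DependencyParse(tuple(current)))
                current = []
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ValueError(f"malformed CoNLL-U line: {line!r}")
        if "-" in cols[0] or "." in cols[0]:
            continue
        current.append(
            ParseToken(
                form=cols[1],
                position=int(cols[0]),
                head=int(cols[6]),
                is_punct=cols[3] == "PUNCT",
                deprel=cols[7],
            )
        )
    if current:
        sentences.append(DependencyParse(tuple(current)))
    return sentences


def write_conllu(parses: Iterable[DependencyParse]) -> str:
    """Serialize parses back to CoNLL-U text (unused columns as ``_``)."""
    blocks = []
    for parse in parses:
        lines = [
            "\t".join(
                [
                    str(t.position),
                    t.form,
                    "_",
                    "PUNCT" if t.is_punct else "X",
                    "_",
                    "_",
                    str(t.head),
                    t.deprel,
                    "_",
                    "_",
                ]
            )
            for t in parse.tokens
        ]
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
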