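"""SMILES tokenizer and vocabulary for CHUCKLES peptide strings.

Maximal-munch tokenization: bracket atoms ``[...]`` are single tokens, as are
the two-letter halogens, ``%nn`` ring labels, the mask ``?`` and the residue
separator ``|``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

PAD, START, END = "<pad>", "^", "$"

_TOKEN_RE = re.compile(r"\[[^\]]+\]|Br|Cl|%\d{2}|\?|\||.")
_SINGLE_OK = set("BCNOPSFIbcnops123456789()=#/\\+-@?|.")


class TokenizationError(ValueError):
    pass


def tokenize(s: str) -> list[str]:
    out = []
    pos = 0
    for m in _TOKEN_RE.finditer(s):
        if m.start() != pos:
            raise TokenizationError(f"unknown character at offset {pos}: {s[pos]!r}")
        tok = m.group(0)
        if len(tok) == 1 and tok not in _SINGLE_OK:
            raise TokenizationError(f"unknown character at offset {m.start()}: {tok!r}")
        out.append(tok)
        pos = m.end()
    if pos != len(s):
        raise TokenizationError(f"unknown character at offset {pos}: {s[pos]!r}")
    return out


def detokenize(tokens: Sequence[str]) -> str:
    return "".join(t for t in tokens if t not in (PAD, START, END))


@dataclass(frozen=True)
class Vocabulary:
    tokens: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {t: i for i, t in enumerate(self.tokens)}
        )

    def __len__(self):
        return len(self.tokens)

    @property
    def pad(self) -> int:
        return self._index[PAD]

    @property
    def start(self) -> int:
        return self._index[START]

    @property
    def end(self) -> int:
        return self._index[END]

    def encode(self, s: str, add_start=False, add_end=False) -> list[int]:
        toks = tokenize(s)
        try:
            ids = [self._index[t] for t in toks]
        except KeyError as e:
            raise TokenizationError(f"token {e.args[0]!r} not in vocabulary") from None
        if add_start:
            ids = [self.start] + ids
        if add_end:
            ids = ids + [self.end]
        return ids

    def decode(self, ids: Iterable[int]) -> str:
        return detokenize([self.tokens[i] for i in ids])

    @classmethod
    def build(cls, strings: Iterable[str]) -> "Vocabulary":
        seen: set[str] = set()
        for s in strings:
            seen.update(tokenize(s))
        return cls(tokens=(PAD, START, END) + tuple(sorted(seen)))

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls(tokens=tuple(Path(path).read_text().splitlines()))
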