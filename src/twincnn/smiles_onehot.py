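"""One-hot grid encoding of canonical SMILES strings.

A drug's SMILES string is tokenized into chemically meaningful symbols
(bracket atoms such as ``[Au]`` are single tokens, as are the two-letter
halogens ``Cl`` and ``Br`` outside brackets; every other character stands
alone).  A corpus-wide :class:`TokenVocabulary` maps each symbol to a row of
a binary symbol x position grid: entry (i, j) is 1 iff symbol i occupies
position j.  Strings shorter than the grid width are left-aligned and padded
on the right with a dedicated space token, so every column of the grid
activates exactly one row.  Each row is later consumed as a separate input
channel by the 1D convolutional drug branch, which keeps convolution within
a single chemical symbol.

The module also provides the three encoding perturbations used to probe
whether a trained network exploits chemistry or merely statistics: shuffling
symbol rows, rotating position columns around a cut point, and shuffling
position columns.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PAD_TOKEN",
    "MalformedSmilesError",
    "OutOfVocabularyError",
    "TokenVocabulary",
    "EncoderConfig",
    "DrugOneHot",
    "tokenize",
    "build_vocabulary",
    "encode",
    "decode",
    "encode_corpus",
    "shuffle_symbol_rows",
    "rotate_positions",
    "shuffle_positions",
    "save_encodings",
    "load_encodings",
]

#: Padding symbol occupying its own vocabulary row, so padded columns stay one-hot.
PAD_TOKEN = " "

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]|Cl|Br|.")


class MalformedSmilesError(ValueError):
    """Raised for structurally invalid SMILES input (e.g. unbalanced brackets)."""


class OutOfVocabularyError(KeyError):
    """Raised when a SMILES contains a token absent from the vocabulary."""


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into symbol tokens.

    Bracket atoms (``[...]``) form single tokens; the two-letter organic
    subset halogens ``Cl`` and ``Br`` outside brackets form single tokens;
    every other character is its own token.  Concatenating the returned
    tokens reproduces the input exactly.

    Raises
    ------
    MalformedSmilesError
        If the input is empty or brackets are unbalanced; the message names
        the offending position.
    """
    if not smiles:
        raise MalformedSmilesError("empty SMILES string")
    depth = 0
    for pos, ch in enumerate(smiles):
        if ch == "[":
            depth += 1
            if depth > 1:
                raise MalformedSmilesError(f"nested '[' at position {pos}")
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise MalformedSmilesError(f"unmatched ']' at position {pos}")
    if depth != 0:
        raise MalformedSmilesError(
            f"unclosed '[' at position {smiles.rindex('[')}"
        )
    return _TOKEN_RE.findall(smiles)


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered set of SMILES tokens defining the rows of the one-hot grid.

    Tokens are sorted lexicographically for reproducibility; the padding
    token is always present.  ``index_of`` is a bijection token -> row.
    """

    tokens: tuple[str, ...]
    index_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        if PAD_TOKEN not in self.tokens:
            raise ValueError("padding token missing from vocabulary")
        object.__setattr__(
            self, "index_of", {t: i for i, t in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index_of

    @property
    def pad_index(self) -> int:
        return self.index_of[PAD_TOKEN]


def build_vocabulary(corpus: Iterable[str]) -> TokenVocabulary:
    """Build the sorted token vocabulary over a SMILES corpus plus padding."""
    seen: set[str] = {PAD_TOKEN}
    n = 0
    for smiles in corpus:
        seen.update(tokenize(smiles))
        n += 1
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return TokenVocabulary(tuple(sorted(seen)))


@dataclass(frozen=True)
class EncoderConfig:
    """Fixed grid geometry: vocabulary rows x ``max_len`` position columns.

    ``max_len`` must cover the longest tokenized SMILES in the corpus; longer
    inputs are rejected rather than truncated.
    """

    vocabulary: TokenVocabulary
    max_len: int = 188

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ValueError("max_len must be positive")

    @classmethod
    def from_corpus(
        cls, corpus: Sequence[str], max_len: int | None = None
    ) -> "EncoderConfig":
        """Derive vocabulary (and, if unset, max_len) from the corpus itself."""
        vocab = build_vocabulary(corpus)
        if max_len is None:
            max_len = max(len(tokenize(s)) for s in corpus)
        return cls(vocabulary=vocab, max_len=max_len)


@dataclass(frozen=True)
class DrugOneHot:
    """Binary symbol x position matrix for one drug (rows = vocabulary tokens)."""

    matrix: np.ndarray
    drug_id: str
    smiles: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("one-hot matrix must be 2-dimensional")
        object.__setattr__(self, "matrix", m)


def encode(smiles: str, config: EncoderConfig, drug_id: str = "") -> DrugOneHot:
    """Encode a SMILES string onto the one-hot grid.

    Columns 0..L-1 hold the L tokens in order; remaining columns activate the
    padding row, so every column sums to exactly 1.
    """
    tokens = tokenize(smiles)
    vocab = config.vocabulary
    if len(tokens) > config.max_len:
        raise ValueError(
            f"tokenized length {len(tokens)} exceeds max_len {config.max_len}"
        )
    matrix = np.zeros((len(vocab), config.max_len), dtype=np.uint8)
    for j, tok in enumerate(tokens):
        try:
            matrix[vocab.index_of[tok], j] = 1
        except KeyError:
            raise OutOfVocabularyError(
                f"token {tok!r} not in vocabulary"
            ) from None
    matrix[vocab.pad_index, len(tokens):] = 1
    return DrugOneHot(matrix=matrix, drug_id=drug_id, smiles=smiles)


def decode(x: DrugOneHot, vocabulary: TokenVocabulary) -> list[str]:
    """Invert :func:`encode`: argmax per column, padding stripped from the right."""
    rows = np.argmax(x.matrix, axis=0)
    tokens = [vocabulary.tokens[i] for i in rows]
    while tokens and tokens[-1] == PAD_TOKEN:
        tokens.pop()
    return tokens


def encode_corpus(
    smiles_by_id: dict[str, str], config: EncoderConfig
) -> dict[str, DrugOneHot]:
    return {
        drug_id: encode(s, config, drug_id=drug_id)
        for drug_id, s in smiles_by_id.items()
    }


def _check_permutation(permutation: Sequence[int], n: int, what: str) -> np.ndarray:
    perm = np.asarray(permutation, dtype=np.intp)
    if perm.shape != (n,) or sorted(perm.tolist()) != list(range(n)):
        raise ValueError(f"{what} permutation is not a bijection over 0..{n - 1}")
    return perm


def shuffle_symbol_rows(x: DrugOneHot, permutation: Sequence[int]) -> DrugOneHot:
    """Relabel symbols: row i of the output is row permutation[i] of the input."""
    perm = _check_permutation(permutation, x.matrix.shape[0], "row")
    return DrugOneHot(matrix=x.matrix[perm, :], drug_id=x.drug_id, smiles=x.smiles)


def rotate_positions(x: DrugOneHot, cut: int) -> DrugOneHot:
    """Cut the position axis at ``cut`` and swap the two pieces."""
    n = x.matrix.shape[1]
    if not 0 <= cut <= n:
        raise ValueError(f"cut {cut} outside 0..{n}")
    return DrugOneHot(
        matrix=np.concatenate([x.matrix[:, cut:], x.matrix[:, :cut]], axis=1),
        drug_id=x.drug_id,
        smiles=x.smiles,
    )


def shuffle_positions(x: DrugOneHot, permutation: Sequence[int]) -> DrugOneHot:
    """Shuffle position columns: column j of the output is column permutation[j]."""
    perm = _check_permutation(permutation, x.matrix.shape[1], "column")
    return DrugOneHot(matrix=x.matrix[:, perm], drug_id=x.drug_id, smiles=x.smiles)


def save_encodings(
    encodings: dict[str, DrugOneHot], config: EncoderConfig, out_dir: str | Path
) -> Path:
    """Write stacked encodings as a binary array plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    drug_ids = sorted(encodings)
    stack = np.stack([encodings[d].matrix for d in drug_ids]).astype(np.uint8)
    np.save(out / "onehot.npy", stack)
    sidecar = {
        "drug_ids": drug_ids,
        "smiles": {d: encodings[d].smiles for d in drug_ids},
        "vocabulary": list(config.vocabulary.tokens),
        "max_len": config.max_len,
    }
    (out / "encoder.json").write_text(json.dumps(sidecar, indent=1))
    return out


def load_encodings(in_dir: str | Path) -> tuple[dict[str, DrugOneHot], EncoderConfig]:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "encoder.json").read_text())
    stack = np.load(in_dir / "onehot.npy")
    config = EncoderConfig(
        vocabulary=TokenVocabulary(tuple(sidecar["vocabulary"])),
        max_len=int(sidecar["max_len"]),
    )
    encodings = {
        d: DrugOneHot(matrix=stack[i], drug_id=d, smiles=sidecar["smiles"][d])
        for i, d in enumerate(sidecar["drug_ids"])
    }
    return encodings, config
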