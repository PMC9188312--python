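"""One-hot encoding of protein sequences into fixed-size matrices.

Each residue becomes a 20-dimensional indicator vector; a sequence of
length L becomes an ``len_w x 20`` matrix: positions beyond ``len_w`` are
truncated (the N-terminal prefix is kept) and sequences shorter than
``len_w`` are zero-padded, the pad symbol '-' being the all-zero vector.
Non-standard residues (X, B, Z, ...) likewise map to the zero vector, since
the encoding defines exactly 20 one-hot symbols plus the zero pad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phagemark.sequence_io import ProteinRecord

#: Canonical amino acids in alphabetical one-letter order.  Any fixed order
#: is equivalent for the model, but the order is serialized with trained
#: models so that encodings are reproducible across sessions.
DEFAULT_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Default window length: marker-protein lengths almost never exceed 900
#: residues, so 900 captures nearly all sequences without truncation.
DEFAULT_LEN_W = 900

PLACEHOLDER = "?"


@dataclass(frozen=True)
class EncodingSpec:
    """Alphabet order and window length defining the one-hot layout."""

    alphabet: str = DEFAULT_ALPHABET
    len_w: int = DEFAULT_LEN_W

    def __post_init__(self) -> None:
        if len(self.alphabet) != 20 or len(set(self.alphabet)) != 20:
            raise ValueError("alphabet must contain 20 unique letters")
        if self.len_w < 1:
            raise ValueError("len_w must be >= 1")

    def char_lookup(self) -> np.ndarray:
        """ASCII -> column index table; -1 for symbols outside the alphabet."""
        table = np.full(128, -1, dtype=np.int64)
        for col, aa in enumerate(self.alphabet):
            table[ord(aa)] = col
        return table


@dataclass
class EncodedSequence:
    """A ``len_w x 20`` one-hot matrix plus the pre-truncation length."""

    matrix: np.ndarray
    true_length: int

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(f"matrix must be len_w x 20, got {self.matrix.shape}")


def _indices(seq: str, spec: EncodingSpec) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return spec.char_lookup()[codes]


def encode_sequence(seq: str, spec: EncodingSpec | None = None) -> EncodedSequence:
    """One-hot encode a single amino-acid string.

    Row i is the indicator of ``seq[i]`` for i < min(L, len_w); letters
    outside the 20-letter alphabet give an all-zero row; the tail beyond
    ``len_w`` is dropped and short sequences are zero-padded.
    """
    spec = spec or EncodingSpec()
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    true_length = len(seq)
    idx = _indices(seq[: spec.len_w], spec)
    mat = np.zeros((spec.len_w, 20), dtype=np.float32)
    pos = np.nonzero(idx >= 0)[0]
    mat[pos, idx[pos]] = 1.0
    return EncodedSequence(matrix=mat, true_length=true_length)


def encode_batch(
    records: list[ProteinRecord] | list[str], spec: EncodingSpec | None = None
) -> tuple[np.ndarray, list[str]]:
    """Encode records into a stacked ``(n, len_w, 20)`` array.

    Returns the array and the parallel list of record ids (sequence strings
    are their own ids when raw strings are passed).  Row order matches
    input order.
    """
    spec = spec or EncodingSpec()
    if not records:
        raise ValueError("encode_batch requires at least one record")
    ids: list[str] = []
    out = np.zeros((len(records), spec.len_w, 20), dtype=np.float32)
    for i, rec in enumerate(records):
        if isinstance(rec, ProteinRecord):
            rid, seq = rec.id, rec.sequence
        else:
            rid, seq = rec, rec
        try:
            out[i] = encode_sequence(seq, spec).matrix
        except ValueError as exc:
            raise ValueError(f"record {rid!r}: {exc}") from exc
        ids.append(rid)
    return out, ids


def decode_matrix(enc: EncodedSequence, spec: EncodingSpec | None = None) -> str:
    """Invert :func:`encode_sequence` up to truncation.

    Zero rows inside the informative prefix decode to '?', the placeholder
    for pad/non-alphabet symbols.  A row with more than a single 1 is
    rejected as an invalid matrix.
    """
    spec = spec or EncodingSpec()
    mat = enc.matrix
    sums = mat.sum(axis=1)
    if np.any(sums > 1):
        raise ValueError("invalid one-hot matrix: a row sums to more than 1")
    n = min(enc.true_length, spec.len_w)
    alpha = np.array(list(spec.alphabet))
    cols = mat[:n].argmax(axis=1)
    letters = alpha[cols]
    letters[sums[:n] == 0] = PLACEHOLDER
    return "".join(letters)
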