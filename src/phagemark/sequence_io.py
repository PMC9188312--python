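"""FASTA input/output and labeled protein datasets.

Records carry the 20 canonical amino acids plus the tolerated symbols
``X B Z J U O - *`` that real gene-caller output contains; non-standard
residues are kept here and mapped to zero vectors at encoding time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

OTHERS = "others"

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
TOLERATED = "XBZJUO-*"
_VALID_CHARS = set(CANONICAL_AA) | set(TOLERATED)
_WS = re.compile(r"\s+")


class FastaParseError(ValueError):
    """Malformed FASTA input (reported with a line number)."""


def clean_sequence(seq: str) -> str:
    """Upper-case, strip whitespace, drop trailing stop symbols ('*').

    Idempotent: ``clean_sequence(clean_sequence(s)) == clean_sequence(s)``.
    """
    s = _WS.sub("", seq).upper()
    return s.rstrip("*")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its FASTA identifier and description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence after cleaning")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Protein records with one category label each.

    ``category_order`` lists every category, with the reserved catch-all
    ``"others"`` always last; the output layer of the classifier is indexed
    by this order.
    """

    records: list[ProteinRecord]
    labels: list[str]
    category_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels differ in length")
        if not self.category_order:
            seen: list[str] = []
            for lab in self.labels:
                if lab not in seen:
                    seen.append(lab)
            self.category_order = order_with_others_last(seen)
        extra = set(self.labels) - set(self.category_order)
        if extra:
            raise ValueError(f"labels outside category_order: {sorted(extra)}")
        if OTHERS not in self.category_order:
            self.category_order = list(self.category_order) + [OTHERS]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def target_categories(self) -> list[str]:
        """Categories of interest, i.e. everything except "others"."""
        return [c for c in self.category_order if c != OTHERS]

    def label_indices(self) -> list[int]:
        idx = {c: i for i, c in enumerate(self.category_order)}
        return [idx[lab] for lab in self.labels]


def order_with_others_last(categories: Sequence[str]) -> list[str]:
    """Preserve input order but force "others" to the final slot."""
    out = [c for c in categories if c != OTHERS]
    out.append(OTHERS)
    return out


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into cleaned :class:`ProteinRecord` objects.

    Sequences may span multiple lines.  Raises :class:`FastaParseError` with
    a line number for sequence data before any header, and ``ValueError``
    listing duplicates when two entries share an id.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    header: tuple[str, str] | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid, desc = header
        seq = clean_sequence("".join(chunks))
        if not seq:
            raise FastaParseError(f"{path}: entry {rid!r} has an empty sequence")
        records.append(ProteinRecord(id=rid, sequence=seq, description=desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].strip()
                if not head:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                rid, _, desc = head.partition(" ")
                header = (rid, desc.strip())
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
    flush()

    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate record ids: {dupes}")
    if not records:
        logger.warning("%s: empty FASTA file", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA; a record with no description gets a bare ">id"."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_labeled_dataset(fasta_paths_by_category: Mapping[str, str | Path]) -> LabeledDataset:
    """Concatenate one FASTA per category into a :class:`LabeledDataset`.

    Category order follows the mapping's insertion order except that
    "others" is always moved last.  Every category file must contain at
    least one record (training needs one example per class).
    """
    records: list[ProteinRecord] = []
    labels: list[str] = []
    for category, path in fasta_paths_by_category.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"category {category!r}: no such file {path}")
        recs = read_fasta(path)
        if not recs:
            raise ValueError(f"category {category!r}: file {path} contains no records")
        records.extend(recs)
        labels.extend([category] * len(recs))
    order = order_with_others_last(list(fasta_paths_by_category))
    return LabeledDataset(records=records, labels=labels, category_order=order)


def write_predictions_tsv(rows: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write final predictions as TSV: id, predicted_category, log10_loss, accepted, final_category."""
    cols = ["id", "predicted_category", "log10_loss", "accepted", "final_category"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{row[c]:.6f}" if c == "log10_loss" else str(row[c]) for c in cols
                )
                + "\n"
            )
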