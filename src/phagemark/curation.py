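"""Training-set curation filters.

Reusable versions of the rules used to build a marker-protein training set
from an annotated protein database: keyword selection with noise-keyword
exclusion, a within-category length-percentile filter that flags outliers
for manual verification, and seeded subsampling of the huge "others" pool
to tame class imbalance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from phagemark.sequence_io import OTHERS, ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_TARGET_KEYWORDS = {
    "Portal": ["portal"],
    "TerL": ["large terminase subunit", "terminase large subunit"],
    "TerS": ["small terminase subunit", "terminase small subunit"],
}
DEFAULT_NOISE_KEYWORDS = ["hypothetical", "possible", "like", "predicted"]


@dataclass
class CurationRules:
    """Keyword and length-filter settings.

    Matching is case-insensitive substring on the record description.
    Noise keywords are matched on word boundaries by default so that e.g.
    "like" rejects "portal-like protein" but not "unlikely".
    """

    target_keywords: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_TARGET_KEYWORDS.items()}
    )
    noise_keywords: list[str] = field(default_factory=lambda: list(DEFAULT_NOISE_KEYWORDS))
    length_quantiles: tuple[float, float] = (0.05, 0.95)
    others_sample_size: int = 20000
    seed: int = 0
    noise_word_boundary: bool = True

    def __post_init__(self) -> None:
        low, high = self.length_quantiles
        if not (0.0 <= low < high <= 1.0):
            raise ValueError(f"need 0 <= low < high <= 1, got {self.length_quantiles}")
        for cat, phrases in self.target_keywords.items():
            if not phrases or any(not p for p in phrases):
                raise ValueError(f"category {cat!r} has an empty keyword phrase")
        if OTHERS in self.target_keywords:
            raise ValueError('"others" is reserved and cannot carry target keywords')


def _matches_noise(description: str, rules: CurationRules) -> bool:
    desc = description.lower()
    for kw in rules.noise_keywords:
        if rules.noise_word_boundary:
            if re.search(rf"\b{re.escape(kw.lower())}\b", desc):
                return True
        elif kw.lower() in desc:
            return True
    return False


def keyword_select(
    records: Sequence[ProteinRecord], rules: CurationRules | None = None
) -> tuple[list[tuple[ProteinRecord, str]], list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Assign categories by description keywords.

    Returns ``(labeled, others_candidates, rejected)``: a record is
    labeled category c iff its description contains a target phrase for c
    and no noise keyword; records matching phrases of several categories
    are rejected as "ambiguous", noise matches as "noise:<keyword>";
    records matching nothing become "others" candidates.  Deterministic
    and independent of record order.
    """
    rules = rules or CurationRules()
    labeled: list[tuple[ProteinRecord, str]] = []
    others: list[ProteinRecord] = []
    rejected: list[tuple[ProteinRecord, str]] = []
    for rec in records:
        desc = rec.description.lower()
        hits = [cat for cat, phrases in rules.target_keywords.items()
                if any(p.lower() in desc for p in phrases)]
        if not hits:
            others.append(rec)
            continue
        if _matches_noise(rec.description, rules):
            noisy = next(kw for kw in rules.noise_keywords
                         if (re.search(rf"\b{re.escape(kw.lower())}\b", desc)
                             if rules.noise_word_boundary else kw.lower() in desc))
            rejected.append((rec, f"noise:{noisy}"))
            continue
        if len(hits) > 1:
            rejected.append((rec, "ambiguous"))
            continue
        labeled.append((rec, hits[0]))
    return labeled, others, rejected


def length_percentile_filter(
    records: Sequence[ProteinRecord], low: float = 0.05, high: float = 0.95
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Flag records whose length is outside the category's central quantiles.

    Quantiles interpolate between order statistics at Hazen plotting
    positions (position q*n - 1/2, clamped to the extremes), so with only
    two records nothing is ever flagged.  Records strictly below the low
    quantile or strictly above the high one are flagged for verification
    (callers may re-label flagged records "others" after checking them).
    ``kept + flagged`` partitions the input.
    """
    if len(records) < 2:
        raise ValueError("length filter needs at least 2 records")
    if not (0.0 <= low < high <= 1.0):
        raise ValueError(f"need 0 <= low < high <= 1, got ({low}, {high})")
    lengths = np.array([len(r) for r in records], dtype=float)
    lo_q, hi_q = np.quantile(lengths, [low, high], method="hazen")
    kept, flagged = [], []
    for rec, L in zip(records, lengths):
        (flagged if (L < lo_q or L > hi_q) else kept).append(rec)
    return kept, flagged


def subsample_others(
    records: Sequence[ProteinRecord], n: int = 20000, seed: int = 0
) -> list[ProteinRecord]:
    """Seeded uniform subsample without replacement of the "others" pool.

    Returns min(n, pool) records (with a warning when the pool is smaller
    than requested); records are returned unmodified, in draw order.
    """
    records = list(records)
    if n >= len(records):
        if n > len(records):
            logger.warning(
                "requested %d others but pool has only %d; returning all", n, len(records)
            )
        return records
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    return [records[i] for i in idx]
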