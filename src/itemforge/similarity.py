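"""Overfit screening by normalized Levenshtein similarity.

A generative model trained on a small item bank will sometimes reproduce
its training items nearly verbatim.  As a proxy for such overfit, each
candidate stem is compared against every training stem with the similarity
index

    s(a, b) = 1 - d(a, b) / max(|a|, |b|)

where d is the unit-cost Levenshtein (edit) distance.  s ranges over
[0, 1]; s = 1 iff the strings are identical.  Candidates whose most similar
training stem reaches a threshold (default .90) are treated as largely
identical to the training data and discarded.  Strings are compared as
stored — case and terminal punctuation included.

Edit distances are computed by edlib; the index, nearest-neighbour scan and
filtering policy live here.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import edlib
import numpy as np

__all__ = [
    "SimilarityRecord",
    "FilterSummary",
    "levenshtein",
    "similarity_index",
    "round_half_up",
    "nearest_training_item",
    "filter_overfit",
    "dedupe_and_single_label",
]

DEFAULT_THRESHOLD = 0.90


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance: minimal number of single-character
    insertions, deletions, or substitutions turning one string into the
    other."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


def similarity_index(a: str, b: str, denominator: str = "max") -> float:
    """Inverted, length-normalized Levenshtein similarity in [0, 1].

    ``denominator="max"`` (default) divides by the longer string's length;
    ``"mean"`` divides by the average length.  Undefined when both strings
    are empty.
    """
    if not a and not b:
        raise ValueError("similarity of two empty strings is undefined")
    d = levenshtein(a, b)
    if denominator == "max":
        denom = max(len(a), len(b))
    elif denominator == "mean":
        denom = (len(a) + len(b)) / 2
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return 1.0 - d / denom


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round-half-up at the given number of decimals (so .945 -> .95),
    matching conventional reporting of similarity coefficients."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SimilarityRecord:
    """A candidate stem, its most similar training stem, and the score."""

    candidate: str
    nearest: str
    distance: int
    similarity: float


@dataclass(frozen=True)
class FilterSummary:
    n_pool: int
    n_discarded: int
    proportion_discarded: float
    mean_similarity: float
    sd_similarity: float
    threshold: float


def nearest_training_item(
    candidate: str, training_stems: Sequence[str], denominator: str = "max"
) -> SimilarityRecord:
    """Most similar training stem; ties go to the earliest corpus entry."""
    if not training_stems:
        raise ValueError("training stem set is empty")
    best: SimilarityRecord | None = None
    for stem in training_stems:
        s = similarity_index(candidate, stem, denominator)
        if best is None or s > best.similarity:
            best = SimilarityRecord(
                candidate=candidate,
                nearest=stem,
                distance=levenshtein(candidate, stem),
                similarity=s,
            )
    assert best is not None
    return best


def filter_overfit(
    pool: Sequence[str],
    training_stems: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
    denominator: str = "max",
) -> tuple[list[str], list[SimilarityRecord], list[SimilarityRecord], FilterSummary]:
    """Discard candidates whose nearest-training similarity is >= threshold.

    Returns (kept stems, kept records, discarded records, summary); every
    decision carries its SimilarityRecord.  An empty pool yields an empty
    result, not an error.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    kept: list[str] = []
    kept_records: list[SimilarityRecord] = []
    discarded: list[SimilarityRecord] = []
    sims: list[float] = []
    for cand in pool:
        rec = nearest_training_item(cand, training_stems, denominator)
        sims.append(rec.similarity)
        if rec.similarity >= threshold:
            discarded.append(rec)
        else:
            kept.append(cand)
            kept_records.append(rec)
    n = len(pool)
    summary = FilterSummary(
        n_pool=n,
        n_discarded=len(discarded),
        proportion_discarded=len(discarded) / n if n else 0.0,
        mean_similarity=float(np.mean(sims)) if sims else float("nan"),
        sd_similarity=float(np.std(sims, ddof=1)) if len(sims) > 1 else float("nan"),
        threshold=threshold,
    )
    return kept, kept_records, discarded, summary


def dedupe_and_single_label(
    pool: Sequence[tuple[Sequence[str], str]],
) -> tuple[list[tuple[tuple[str, ...], str]], dict[str, int]]:
    """Collapse exact-duplicate stems (first occurrence wins) and drop items
    generated under multi-label prompts.

    ``pool`` holds (labels, stem) pairs; returns the surviving pairs and a
    count report {'n_in', 'n_duplicates', 'n_multilabel', 'n_out'}.
    """
    seen: set[str] = set()
    out: list[tuple[tuple[str, ...], str]] = []
    n_dup = n_multi = 0
    for labels, stem in pool:
        labels = tuple(labels)
        if len(labels) != 1:
            n_multi += 1
            continue
        if stem in seen:
            n_dup += 1
            continue
        seen.add(stem)
        out.append((labels, stem))
    report = {
        "n_in": len(pool),
        "n_duplicates": n_dup,
        "n_multilabel": n_multi,
        "n_out": len(out),
    }
    return out, report
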