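"""Configuration, file formats, and run orchestration.

File formats:

* corpus CSV — columns ``labels`` (semicolon-separated) and ``stem``; or a
  plain-text encoded format with one delimited pattern string per line;
* Likert CSV — header row of item names, one respondent per row, with an
  optional JSON/YAML sidecar mapping items to constructs and keying;
* generated-items CSV — labels, stem, logprob, decoding settings, seed,
  parse status;
* filter-report CSV — candidate, nearest training stem, distance,
  similarity, decision, threshold;
* checkpoint — versioned archive of config + named weight arrays
  (see transformer.save_checkpoint).

Reproducibility: one global seed fans out to per-stage seeds by hashing the
stage name (crc32), so each stage can be rerun independently yet two runs
with the same resolved config produce identical artifacts.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decoding import DecodingConfig, GeneratedItem
from .encoding import (
    DEFAULT_DELIMITERS,
    EncodedExample,
    ParseFailure,
    decode_example,
    encode_example,
)
from .psychometrics import LikertMatrix
from .similarity import SimilarityRecord
from .transformer import ModelConfig

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "read_corpus",
    "write_corpus",
    "read_likert",
    "write_likert",
    "write_generated_items",
    "write_filter_report",
]


class FileFormatError(ValueError):
    """A data file violates its declared format; message carries the line."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (stable, < 2**31)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Resolved settings for a full run; serializable to/from YAML."""

    corpus_path: str = "corpus.csv"
    out_dir: str = "run"
    delimiters: tuple[str, str] = DEFAULT_DELIMITERS
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    decoding: dict = field(default_factory=dict)  # DecodingConfig overrides
    train_steps: int = 2000
    learning_rate: float = 5e-4
    filter_threshold: float = 0.90
    n_generate: int = 20
    seed: int = 0

    def model_config(self, vocab_size: int, n_ctx: int) -> ModelConfig:
        kwargs = dict(self.model)
        kwargs.setdefault("seed", stage_seed(self.seed, "train"))
        return ModelConfig(vocab_size=vocab_size, n_ctx=n_ctx, **kwargs)

    def decoding_config(self) -> DecodingConfig:
        kwargs = dict(self.decoding)
        kwargs.setdefault("seed", stage_seed(self.seed, "generate"))
        return DecodingConfig(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise FileFormatError(f"unknown config keys: {sorted(unknown)}")
        if "delimiters" in raw:
            raw["delimiters"] = tuple(raw["delimiters"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Corpus files
# ---------------------------------------------------------------------------


def read_corpus(
    path: str | Path, delimiters: tuple[str, str] = DEFAULT_DELIMITERS
) -> list[EncodedExample]:
    """Read a corpus as CSV (columns labels, stem) or encoded text lines."""
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        missing = {"labels", "stem"} - set(df.columns)
        if missing:
            raise FileFormatError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        out = []
        for i, row in df.iterrows():
            labels = [x.strip() for x in str(row["labels"]).split(";") if x.strip()]
            try:
                out.append(encode_example(labels, str(row["stem"]), delimiters))
            except ValueError as exc:
                raise FileFormatError(f"{path} line {i + 2}: {exc}") from exc
        return out
    out = []
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parsed = decode_example(line, delimiters)
        if isinstance(parsed, ParseFailure):
            raise FileFormatError(f"{path} line {i}: {parsed.kind.value}")
        out.append(parsed)
    return out


def write_corpus(
    path: str | Path, corpus: list[EncodedExample], encoded: bool = False
) -> None:
    path = Path(path)
    if encoded or path.suffix.lower() not in (".csv", ".tsv"):
        path.write_text(
            "\n".join(ex.encoded for ex in corpus) + "\n", encoding="utf-8"
        )
        return
    df = pd.DataFrame(
        {"labels": [";".join(ex.labels) for ex in corpus],
         "stem": [ex.stem for ex in corpus]}
    )
    df.to_csv(path, index=False, sep="\t" if path.suffix.lower() == ".tsv" else ",")


# ---------------------------------------------------------------------------
# Likert response files
# ---------------------------------------------------------------------------


def read_likert(
    path: str | Path, sidecar: str | Path | None = None, n_categories: int = 5
) -> LikertMatrix:
    """Likert CSV: header of item names, one respondent per row.

    The optional sidecar (YAML or JSON) maps item names to ``construct``
    and ``keying`` entries.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise FileFormatError(f"{path}: no response rows")
    constructs: list[str] = []
    keying: list[str] = []
    if sidecar is not None:
        meta = yaml.safe_load(Path(sidecar).read_text(encoding="utf-8"))
        for name in df.columns:
            entry = meta.get(name, {})
            constructs.append(str(entry.get("construct", "")))
            keying.append(str(entry.get("keying", "+")))
    try:
        return LikertMatrix(
            values=df.to_numpy(dtype=float),
            item_names=list(df.columns),
            constructs=constructs,
            keying=keying,
            n_categories=n_categories,
        )
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_likert(
    path: str | Path, data: LikertMatrix, sidecar: str | Path | None = None
) -> None:
    pd.DataFrame(data.values, columns=data.item_names).to_csv(path, index=False)
    if sidecar is not None:
        meta = {
            name: {"construct": c, "keying": k}
            for name, c, k in zip(data.item_names, data.constructs, data.keying)
        }
        Path(sidecar).write_text(yaml.safe_dump(meta), encoding="utf-8")


# ---------------------------------------------------------------------------
# Generated items and filter reports
# ---------------------------------------------------------------------------


def write_generated_items(path: str | Path, items: list[GeneratedItem]) -> None:
    rows = []
    for it in items:
        rows.append(
            {
                "labels": ";".join(it.labels),
                "stem": it.stem,
                "logprob": it.logprob,
                "strategy": it.config.strategy,
                "tau": it.config.tau,
                "top_k": it.config.top_k,
                "top_p": it.config.top_p,
                "n_beams": it.config.n_beams,
                "seed": it.config.seed,
                "parse_status": it.parse_status,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_filter_report(
    path: str | Path,
    kept: list[SimilarityRecord],
    discarded: list[SimilarityRecord],
    threshold: float,
) -> None:
    rows = [
        {
            "candidate": r.candidate,
            "nearest": r.nearest,
            "distance": r.distance,
            "similarity": r.similarity,
            "decision": decision,
            "threshold": threshold,
        }
        for decision, records in (("keep", kept), ("discard", discarded))
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
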