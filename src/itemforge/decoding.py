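"""Conditional generation: greedy search, beam search, multinomial sampling.

The prompt is the partial label pattern (``#Pessimism@``); generation
completes the item stem token by token until the end-of-text symbol or the
length bound.  For sampling, the next-token distribution may be reshaped
before drawing: temperature first (in log space), then top-k truncation,
then nucleus (top-p) truncation, each followed by renormalization over the
surviving support.  Reported log-probabilities always refer to the
*untruncated* model distribution, so scores are comparable across
strategies.

Determinism: greedy and beam search are bit-reproducible via fixed
tie-breaking (higher probability first, then lower token id); sampling is
reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoding import (
    EOT,
    DEFAULT_DELIMITERS,
    ParseFailure,
    Vocab,
    build_prompt,
    decode_example,
)
from .transformer import ModelConfig, TransformerParams, forward

__all__ = [
    "DecodingConfig",
    "GeneratedItem",
    "transform_distribution",
    "sample_next",
    "greedy_generate",
    "beam_generate",
    "sample_generate",
    "generate_items",
]


@dataclass(frozen=True)
class DecodingConfig:
    """Search-heuristic settings; sampling controls only apply when
    ``strategy == "sample"`` and beams only when ``strategy == "beam"``."""

    strategy: str = "greedy"  # "greedy" | "beam" | "sample"
    n_beams: int = 1
    top_k: int = 0  # 0 = off
    top_p: float = 1.0  # 1 = off
    tau: float = 1.0
    max_len: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("greedy", "beam", "sample"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.n_beams < 1:
            raise ValueError("n_beams must be >= 1")
        if self.top_k < 0:
            raise ValueError("top_k must be >= 0 (0 disables)")
        if not 0 < self.top_p <= 1:
            raise ValueError("top_p must lie in (0, 1]")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")


@dataclass
class GeneratedItem:
    """One generated candidate with its provenance."""

    labels: tuple[str, ...]
    stem: str
    token_ids: list[int]
    logprob: float  # joint log-probability under the untruncated model
    config: DecodingConfig
    parse_status: str = "ok"  # "ok" | the malformation category
    truncated: bool = False

    @property
    def parsed_ok(self) -> bool:
        return self.parse_status == "ok"


def transform_distribution(
    p: np.ndarray, tau: float = 1.0, top_k: int = 0, top_p: float = 1.0
) -> np.ndarray:
    """Reshape a next-token distribution for multinomial sampling.

    Temperature rescales in log space (``p**(1/tau)`` renormalized); top-k
    keeps the k most probable tokens; nucleus keeps the smallest
    probability-sorted prefix whose cumulative mass reaches ``top_p``.  Ties
    are broken toward lower token ids; the support is never empty.
    """
    p = np.asarray(p, dtype=float)
    if tau <= 0:
        raise ValueError("temperature must be positive")
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    if not 0 < top_p <= 1:
        raise ValueError("top_p must lie in (0, 1]")
    if p.ndim != 1 or p.size == 0 or np.any(p < 0):
        raise ValueError("p must be a 1-D probability vector")

    if tau != 1.0:
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        shifted = logp / tau
        shifted -= shifted[np.isfinite(shifted)].max()
        p = np.exp(shifted)
        p /= p.sum()

    # stable ordering: descending probability, ascending id on ties
    order = np.lexsort((np.arange(p.size), -p))
    if top_k:
        kill = order[top_k:]
        p = p.copy()
        p[kill] = 0.0
        p /= p.sum()
    if top_p < 1.0:
        order = np.lexsort((np.arange(p.size), -p))
        csum = np.cumsum(p[order])
        # smallest prefix with cumulative mass >= top_p (never empty)
        cut = int(np.searchsorted(csum, top_p, side="left")) + 1
        kill = order[cut:]
        p = p.copy()
        p[kill] = 0.0
        p /= p.sum()
    return p


def sample_next(
    p: np.ndarray, cfg: DecodingConfig, rng: np.random.Generator
) -> int:
    """Draw one token id from the transformed distribution."""
    q = transform_distribution(p, cfg.tau, cfg.top_k, cfg.top_p)
    return int(rng.choice(q.size, p=q))


def _argmax_tiebreak(p: np.ndarray) -> int:
    """Highest probability, lowest id on ties (np.argmax already does)."""
    return int(np.argmax(p))


def greedy_generate(
    params: TransformerParams,
    model_cfg: ModelConfig,
    prompt_ids: Sequence[int],
    max_len: int = 32,
) -> tuple[list[int], float, bool]:
    """Deterministic decoding: the single most probable token each step.

    Returns (full id sequence, joint log-probability of the continuation,
    truncated flag).  Stops on the end-of-text token or after ``max_len``
    generated tokens.
    """
    ids = list(prompt_ids)
    logprob = 0.0
    steps = min(max_len, model_cfg.n_ctx - len(ids))  # respect context bound
    for _ in range(steps):
        p = forward(ids, params, model_cfg)[-1]
        tok = _argmax_tiebreak(p)
        logprob += float(np.log(p[tok]))
        ids.append(tok)
        if tok == EOT:
            return ids, logprob, False
    return ids, logprob, True


def beam_generate(
    params: TransformerParams,
    model_cfg: ModelConfig,
    prompt_ids: Sequence[int],
    n_beams: int,
    max_len: int = 32,
) -> list[tuple[list[int], float, bool]]:
    """Beam search over joint (unnormalized) sequence log-probability.

    Keeps the ``n_beams`` best hypotheses each step; completed hypotheses
    (ending in end-of-text) stay in the pool and stop expanding.  Returns
    hypotheses sorted best-first; ties break toward lexicographically
    smaller token sequences.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    prompt = list(prompt_ids)
    # (ids, logprob, done)
    pool: list[tuple[list[int], float, bool]] = [(prompt, 0.0, False)]
    steps = min(max_len, model_cfg.n_ctx - len(prompt))
    for _ in range(steps):
        if all(done for _, _, done in pool):
            break
        candidates: list[tuple[list[int], float, bool]] = []
        for ids, lp, done in pool:
            if done:
                candidates.append((ids, lp, True))
                continue
            p = forward(ids, params, model_cfg)[-1]
            with np.errstate(divide="ignore"):
                logp = np.log(p)
            for tok in range(p.size):
                if not np.isfinite(logp[tok]):
                    continue
                candidates.append(
                    (ids + [tok], lp + float(logp[tok]), tok == EOT)
                )
        candidates.sort(key=lambda c: (-c[1], c[0]))
        pool = candidates[:n_beams]
    return [
        (ids, lp, not done)
        for ids, lp, done in sorted(pool, key=lambda c: (-c[1], c[0]))
    ]


def sample_generate(
    params: TransformerParams,
    model_cfg: ModelConfig,
    prompt_ids: Sequence[int],
    cfg: DecodingConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[int], float, bool]:
    """Multinomial sampling from the (optionally transformed) distribution.

    The reported log-probability is the sum of log-probabilities of the
    chosen tokens under the untruncated model distribution.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ids = list(prompt_ids)
    logprob = 0.0
    steps = min(cfg.max_len, model_cfg.n_ctx - len(ids))
    for _ in range(steps):
        p = forward(ids, params, model_cfg)[-1]
        tok = sample_next(p, cfg, rng)
        logprob += float(np.log(p[tok]))
        ids.append(tok)
        if tok == EOT:
            return ids, logprob, False
    return ids, logprob, True


def generate_items(
    labels: Sequence[str],
    count: int,
    params: TransformerParams,
    model_cfg: ModelConfig,
    config: DecodingConfig,
    vocab: Vocab,
    delimiters: Sequence[str] = DEFAULT_DELIMITERS,
) -> list[GeneratedItem]:
    """Generate ``count`` candidate items conditioned on construct labels.

    Each candidate is decoded back through the string codec; malformed
    generations are returned flagged with their malformation category, never
    dropped silently.
    """
    prompt = build_prompt(labels, delimiters)
    prompt_ids = vocab.encode_ids(prompt)
    rng = np.random.default_rng(config.seed)
    items: list[GeneratedItem] = []
    for i in range(count):
        if config.strategy == "greedy":
            ids, lp, trunc = greedy_generate(
                params, model_cfg, prompt_ids, config.max_len
            )
        elif config.strategy == "beam":
            hyps = beam_generate(
                params, model_cfg, prompt_ids, config.n_beams, config.max_len
            )
            ids, lp, trunc = hyps[0]
        else:
            ids, lp, trunc = sample_generate(
                params, model_cfg, prompt_ids, config, rng
            )
        text = vocab.decode_ids(ids)
        parsed = decode_example(text, tuple(delimiters))
        if isinstance(parsed, ParseFailure):
            items.append(
                GeneratedItem(
                    labels=tuple(labels),
                    stem="",
                    token_ids=ids,
                    logprob=lp,
                    config=config,
                    parse_status=parsed.kind.value,
                    truncated=trunc,
                )
            )
        else:
            items.append(
                GeneratedItem(
                    labels=tuple(labels),
                    stem=parsed.stem,
                    token_ids=ids,
                    logprob=lp,
                    config=config,
                    parse_status="ok",
                    truncated=trunc,
                )
            )
    return items
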