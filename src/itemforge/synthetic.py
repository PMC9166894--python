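"""Synthetic fixtures: toy item corpora and ordinal response matrices.

Two generators make every pipeline stage testable without external data:

* a probabilistic template grammar producing label-conditioned item stems.
  Each construct owns sentence templates with construct-specific lexical
  slot fillers, so a miniature language model can demonstrably learn the
  label -> stem association (the desk-scale analogue of prompting a
  fine-tuned model with a construct label);
* a one-factor latent-normal response model: respondent trait z ~ N(0, 1),
  item propensity y*_j = lambda_j z + sqrt(1 - lambda_j^2) e with
  e ~ N(0, 1), discretized by ordered thresholds into categories 1..K.
  Marginal category proportions therefore converge to the normal-CDF gaps
  between thresholds.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import DEFAULT_DELIMITERS, EncodedExample, encode_example
from .psychometrics import LikertMatrix

__all__ = [
    "GrammarSpec",
    "ResponseModelSpec",
    "default_grammar",
    "gen_item_corpus",
    "gen_likert",
    "gen_rater_table",
]

#: equidistant default thresholds for K = 5 categories
DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)


@dataclass
class GrammarSpec:
    """Per-construct sentence templates with lexical slot fillers.

    ``templates`` maps construct -> list of template strings with ``{slot}``
    placeholders; ``lexicon`` maps construct -> slot -> filler words.
    """

    templates: dict[str, list[str]]
    lexicon: dict[str, dict[str, list[str]]]
    weights: dict[str, float] | None = None
    delimiters: tuple[str, str] = DEFAULT_DELIMITERS

    def __post_init__(self) -> None:
        for construct, temps in self.templates.items():
            fillers = self.lexicon.get(construct, {})
            for text in temps + [w for ws in fillers.values() for w in ws]:
                for d in self.delimiters:
                    if d in text:
                        raise ValueError(
                            f"grammar text {text!r} contains delimiter {d!r}"
                        )

    @property
    def constructs(self) -> list[str]:
        return list(self.templates)


def default_grammar() -> GrammarSpec:
    """A two-construct toy grammar with disjoint lexical signatures."""
    return GrammarSpec(
        templates={
            "Calmness": ["I {verb} {object}.", "I am {adverb} {adjective}."],
            "Orderliness": ["I {verb} {object}.", "I am {adverb} {adjective}."],
        },
        lexicon={
            "Calmness": {
                "verb": ["enjoy", "seek"],
                "object": ["quiet evenings", "peaceful places"],
                "adverb": ["usually", "rarely"],
                "adjective": ["relaxed", "serene"],
            },
            "Orderliness": {
                "verb": ["organize", "tidy"],
                "object": ["my desk", "my schedule"],
                "adverb": ["always", "often"],
                "adjective": ["structured", "methodical"],
            },
        },
    )


_MEMO_PAIRS = [
    ("Anxiety", "I worry about small things"),
    ("Orderliness", "I keep my room tidy"),
    ("Sociability", "I talk to strangers easily"),
    ("Altruism", "I help people in need"),
    ("Curiosity", "I ask many questions"),
    ("Diligence", "I finish what I start"),
    ("Calmness", "I stay cool under pressure"),
    ("Assertiveness", "I speak my mind freely"),
    ("Modesty", "I avoid bragging about success"),
    ("Imagination", "I daydream about distant worlds"),
    ("Cheerfulness", "I laugh at silly jokes"),
    ("Caution", "I read contracts twice before signing"),
    ("Trust", "I believe people mean well"),
    ("Ambition", "I set very high goals"),
    ("Patience", "I wait in lines calmly"),
    ("Creativity", "I invent games for children"),
    ("Empathy", "I feel the pain of friends"),
    ("Discipline", "I wake up early every day"),
    ("Optimism", "I expect good outcomes tomorrow"),
    ("Resilience", "I recover quickly from setbacks"),
]


def memorization_grammar(n_constructs: int = 20) -> GrammarSpec:
    """A grammar whose constructs each emit exactly one stem.

    With one deterministic stem per label, a model with enough capacity can
    drive the training cross-entropy toward zero, and greedy decoding from
    each label prompt must return that label's stem — the fixture behind
    memorization checks.
    """
    if not 1 <= n_constructs <= len(_MEMO_PAIRS):
        raise ValueError(f"n_constructs must be in 1..{len(_MEMO_PAIRS)}")
    pairs = _MEMO_PAIRS[:n_constructs]
    return GrammarSpec(
        templates={label: ["{p}."] for label, _ in pairs},
        lexicon={label: {"p": [stem]} for label, stem in pairs},
    )


def gen_item_corpus(
    spec: GrammarSpec, n: int, seed: int = 0
) -> list[tuple[tuple[str, ...], str]]:
    """Sample ``n`` (labels, stem) pairs from the grammar, seeded.

    Every returned pair is encodable by the string codec; both constructs
    of the default grammar are guaranteed representation for n >= 2 by
    round-robin construct choice before random filling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    constructs = spec.constructs
    weights = None
    if spec.weights:
        w = np.asarray([spec.weights.get(c, 1.0) for c in constructs], dtype=float)
        weights = w / w.sum()
    out: list[tuple[tuple[str, ...], str]] = []
    seen: set[str] = set()
    for i in range(n):
        if weights is None:
            construct = constructs[i % len(constructs)]
        else:
            construct = constructs[int(rng.choice(len(constructs), p=weights))]
        template = spec.templates[construct][
            int(rng.integers(len(spec.templates[construct])))
        ]
        fillers = {
            slot: words[int(rng.integers(len(words)))]
            for slot, words in spec.lexicon[construct].items()
        }
        stem = template.format(**fillers)
        # validate encodability eagerly
        encode_example([construct], stem, spec.delimiters)
        seen.add(stem)
        out.append(((construct,), stem))
    return out


def corpus_to_examples(
    corpus: list[tuple[tuple[str, ...], str]],
    delimiters: tuple[str, str] = DEFAULT_DELIMITERS,
) -> list[EncodedExample]:
    return [encode_example(list(labels), stem, delimiters) for labels, stem in corpus]


@dataclass
class ResponseModelSpec:
    """One-factor graded response generator settings.

    ``loadings`` gives lambda_j per item (|lambda_j| < 1); ``thresholds``
    one ordered (K-1)-tuple per item (a single tuple is broadcast).
    """

    loadings: tuple[float, ...]
    thresholds: tuple = (DEFAULT_THRESHOLDS,)
    n_respondents: int = 220
    seed: int = 0
    constructs: tuple[str, ...] = ()  # optional block structure, one per item

    def __post_init__(self) -> None:
        lam = np.asarray(self.loadings, dtype=float)
        if np.any(np.abs(lam) >= 1):
            raise ValueError("|loadings| must be < 1")
        th = self.thresholds
        if th and not isinstance(th[0], (tuple, list, np.ndarray)):
            th = (tuple(th),)
        if len(th) == 1:
            th = th * len(self.loadings)
        if len(th) != len(self.loadings):
            raise ValueError("need one threshold tuple per item (or one shared)")
        for t in th:
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"thresholds must be strictly increasing: {t}")
        self.thresholds = tuple(tuple(float(v) for v in t) for t in th)
        if self.constructs and len(self.constructs) != len(self.loadings):
            raise ValueError("constructs must match the number of items")


def gen_likert(spec: ResponseModelSpec) -> LikertMatrix:
    """Ordinal responses from the one-factor latent-normal model, seeded.

    With block structure (``constructs`` set), each construct block gets its
    own independent latent factor; otherwise one common factor drives all
    items.
    """
    rng = np.random.default_rng(spec.seed)
    lam = np.asarray(spec.loadings, dtype=float)
    J = lam.size
    N = spec.n_respondents
    K = len(spec.thresholds[0]) + 1
    if spec.constructs:
        blocks = list(dict.fromkeys(spec.constructs))
        z_block = {c: rng.standard_normal(N) for c in blocks}
        z = np.column_stack([z_block[c] for c in spec.constructs])
    else:
        z = rng.standard_normal(N)[:, None] * np.ones((1, J))
    e = rng.standard_normal((N, J))
    ystar = lam[None, :] * z + np.sqrt(1.0 - lam**2)[None, :] * e
    values = np.ones((N, J), dtype=int)
    for j in range(J):
        for t in spec.thresholds[j]:
            values[:, j] += (ystar[:, j] > t).astype(int)
    return LikertMatrix(
        values=values,
        constructs=list(spec.constructs) if spec.constructs else [],
        n_categories=K,
    )


def gen_rater_table(
    observed_agreement: float | None,
    marginals: tuple[float, ...],
    n: int,
) -> np.ndarray:
    """Integer two-rater R x R agreement table with requested totals.

    ``marginals`` gives the shared category proportions of both raters;
    diagonal mass is set to ``observed_agreement * n`` distributed in
    proportion to the marginals, off-diagonal mass by independence of the
    residual.  ``observed_agreement=None`` builds the exact independence
    table (products of marginals), which yields kappa ~ 0 downstream.
    Raises when the request is infeasible (counts would go negative or
    proportions are inconsistent).
    """
    p = np.asarray(marginals, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("marginal proportions must sum to 1")
    R = p.size
    if observed_agreement is None:
        table = np.round(np.outer(p, p) * n)
    elif not 0 <= observed_agreement <= 1:
        raise ValueError("observed agreement must lie in [0, 1]")
    elif observed_agreement >= 1.0:
        table = np.diag(np.round(p * n))
    else:
        diag = observed_agreement * p
        off_total = 1.0 - observed_agreement
        # distribute disagreement by independence over off-diagonal cells
        outer = np.outer(p, p)
        np.fill_diagonal(outer, 0.0)
        if outer.sum() <= 0:
            raise ValueError("infeasible: no off-diagonal mass available")
        table = outer / outer.sum() * off_total
        np.fill_diagonal(table, diag)
        table = np.round(table * n)
    if np.any(table < 0):
        raise ValueError("infeasible request: negative cell count")
    # fix rounding drift on the largest cell so totals are exact
    drift = int(n - table.sum())
    idx = np.unravel_index(np.argmax(table), table.shape)
    table[idx] += drift
    if table[idx] < 0:
        raise ValueError("infeasible request after rounding")
    return table.astype(int)
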