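"""Segmented training pattern codec and vocabulary layer.

A training example pairs one or more construct labels (short names of the
latent variable an item measures, e.g. ``Anxiety``) with an item stem (the
statement text, e.g. ``I worry about things``).  For conditioning a causal
language model, the pair is flattened into a single delimited string::

    #Anxiety#Neuroticism@I worry about things

where ``#`` precedes each construct label and ``@`` separates the label
block from the stem.  At generation time the partial pattern up to and
including ``@`` (the *prompt*) is fed to the model, which completes the
stem.  This module owns that codec plus the tokenizer/vocabulary that maps
encoded strings to integer id sequences; construct labels are registered as
single vocabulary entries so the model learns each label as one unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_DELIMITERS",
    "ConstructLabel",
    "ItemStem",
    "EncodedExample",
    "ParseFailure",
    "MalformedKind",
    "Vocab",
    "encode_example",
    "decode_example",
    "build_prompt",
    "fit_vocab",
]

#: label delimiter (u_A) and label/stem separator (u_B)
DEFAULT_DELIMITERS: tuple[str, str] = ("#", "@")

# Reserved token ids; stable across save/load.
PAD, UNK, EOT, U_A, U_B = 0, 1, 2, 3, 4
RESERVED_TOKENS = {"<pad>": PAD, "<unk>": UNK, "<eot>": EOT}
N_RESERVED_FIXED = 5  # pad, unk, eot, u_A, u_B


class CodecError(ValueError):
    """Raised when text violates the codec preconditions (delimiter collision,
    empty label list, empty stem)."""


def _check_delims(delimiters: Sequence[str]) -> tuple[str, str]:
    if len(delimiters) != 2 or any(len(d) != 1 for d in delimiters):
        raise CodecError("delimiters must be a pair of single characters")
    u_a, u_b = delimiters
    if u_a == u_b:
        raise CodecError("the two delimiter characters must differ")
    return u_a, u_b


def _clean(text: str, what: str, delimiters: Sequence[str]) -> str:
    text = text.strip()
    if not text:
        raise CodecError(f"{what} must be a nonempty string")
    if "\n" in text:
        raise CodecError(f"{what} {text!r} contains a newline")
    for d in delimiters:
        if d in text:
            raise CodecError(
                f"{what} {text!r} contains the delimiter character {d!r}"
            )
    return text


@dataclass(frozen=True)
class ConstructLabel:
    """Short text name of a psychological construct, e.g. ``Neuroticism``."""

    text: str
    delimiters: tuple[str, str] = DEFAULT_DELIMITERS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "text", _clean(self.text, "construct label", self.delimiters)
        )


@dataclass(frozen=True)
class ItemStem:
    """One-sentence statement text of a rating-scale item."""

    text: str
    delimiters: tuple[str, str] = DEFAULT_DELIMITERS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "text", _clean(self.text, "item stem", self.delimiters)
        )


@dataclass(frozen=True)
class EncodedExample:
    """A (labels, stem) pair plus its delimiter-concatenated string form."""

    labels: tuple[str, ...]
    stem: str
    encoded: str


class MalformedKind(Enum):
    MISSING_SEPARATOR = "missing u_B separator"
    MISSING_LABEL_MARK = "string does not start with u_A"
    EMPTY_LABEL = "empty construct label"
    EMPTY_STEM = "empty stem"


@dataclass(frozen=True)
class ParseFailure:
    """Structured parse-failure result returned by :func:`decode_example`."""

    kind: MalformedKind
    text: str

    def __bool__(self) -> bool:  # falsy so `if result:` means success
        return False


def encode_example(
    labels: Sequence[str | ConstructLabel],
    stem: str | ItemStem,
    delimiters: Sequence[str] = DEFAULT_DELIMITERS,
    sort_labels: bool = False,
) -> EncodedExample:
    """Flatten construct labels and an item stem into the delimited pattern.

    Label order is preserved as given; ``sort_labels=True`` canonicalizes
    the order (useful for deduplicating multi-label corpora).

    >>> encode_example(["Anxiety", "Neuroticism"], "I worry about things").encoded
    '#Anxiety#Neuroticism@I worry about things'
    """
    u_a, u_b = _check_delims(delimiters)
    if not labels:
        raise CodecError("at least one construct label is required")
    if sort_labels:
        labels = sorted(labels, key=lambda l: l.text if isinstance(l, ConstructLabel) else str(l))
    label_texts = tuple(
        lab.text
        if isinstance(lab, ConstructLabel)
        else ConstructLabel(str(lab), (u_a, u_b)).text
        for lab in labels
    )
    stem_text = (
        stem.text if isinstance(stem, ItemStem) else ItemStem(str(stem), (u_a, u_b)).text
    )
    encoded = "".join(u_a + lab for lab in label_texts) + u_b + stem_text
    return EncodedExample(labels=label_texts, stem=stem_text, encoded=encoded)


def decode_example(
    encoded: str, delimiters: Sequence[str] = DEFAULT_DELIMITERS
) -> EncodedExample | ParseFailure:
    """Inverse of :func:`encode_example`; never raises on malformed input.

    Returns an :class:`EncodedExample` when ``encoded`` matches the pattern,
    otherwise a :class:`ParseFailure` naming the malformation.
    """
    u_a, u_b = _check_delims(delimiters)
    if u_b not in encoded:
        return ParseFailure(MalformedKind.MISSING_SEPARATOR, encoded)
    head, _, stem = encoded.partition(u_b)
    if not head.startswith(u_a):
        return ParseFailure(MalformedKind.MISSING_LABEL_MARK, encoded)
    labels = head.split(u_a)[1:]
    if any(not lab.strip() for lab in labels) or not labels:
        return ParseFailure(MalformedKind.EMPTY_LABEL, encoded)
    if not stem.strip():
        return ParseFailure(MalformedKind.EMPTY_STEM, encoded)
    return EncodedExample(
        labels=tuple(lab.strip() for lab in labels),
        stem=stem.strip(),
        encoded=encoded,
    )


def build_prompt(
    labels: Sequence[str | ConstructLabel],
    delimiters: Sequence[str] = DEFAULT_DELIMITERS,
) -> str:
    """Partial pattern up to and including u_B, used as a generation prompt.

    >>> build_prompt(["Pessimism"])
    '#Pessimism@'
    """
    ex = encode_example(labels, "x", delimiters)  # placeholder stem, dropped
    return ex.encoded[: -len("x")]


# ---------------------------------------------------------------------------
# Tokenizer / vocabulary
# ---------------------------------------------------------------------------


@dataclass
class Vocab:
    """Token table mapping encoded strings to integer id sequences.

    Ids 0–4 are reserved (pad, unk, end-of-text, u_A, u_B); registered
    construct labels occupy one id each so the model treats a label as a
    single unit.  Two schemes exist: ``"word"`` splits stems on whitespace
    (punctuation stays attached to its word) and ``"char"`` emits one token
    per character, for very small experiments.
    """

    token_to_id: dict[str, int]
    id_to_token: dict[int, str]
    delimiters: tuple[str, str] = DEFAULT_DELIMITERS
    scheme: str = "word"
    label_set: frozenset[str] = field(default_factory=frozenset)
    oov_count: int = 0  # running count of unknown tokens seen at encode time

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    # -- stem-level tokenization ------------------------------------------
    def _split_stem(self, stem: str) -> list[str]:
        if self.scheme == "char":
            return list(stem)
        return stem.split(" ")

    def _join_stem(self, tokens: list[str]) -> str:
        return ("" if self.scheme == "char" else " ").join(tokens)

    # -- string <-> ids ----------------------------------------------------
    def encode_ids(self, encoded: str, append_eot: bool = True) -> list[int]:
        """Map an encoded training string (or a bare prompt) to token ids."""
        parsed = decode_example(encoded, self.delimiters)
        if isinstance(parsed, ParseFailure):
            if parsed.kind is MalformedKind.EMPTY_STEM:
                # A prompt: labels only, ends with u_B.
                head = encoded[: -len(self.delimiters[1])]
                labels = [t for t in head.split(self.delimiters[0]) if t]
                ids = []
                for lab in labels:
                    ids += [U_A, self._lookup(lab)]
                return ids + [U_B]
            raise CodecError(f"cannot tokenize malformed string: {parsed.kind.value}")
        ids: list[int] = []
        for lab in parsed.labels:
            ids += [U_A, self._lookup(lab)]
        ids.append(U_B)
        ids += [self._lookup(tok) for tok in self._split_stem(parsed.stem)]
        if append_eot:
            ids.append(EOT)
        return ids

    def _lookup(self, token: str) -> int:
        tid = self.token_to_id.get(token)
        if tid is None:
            self.oov_count += 1
            return UNK
        return tid

    def decode_ids(self, ids: Iterable[int]) -> str:
        """Map ids back to the encoded string (stops at end-of-text)."""
        u_a, u_b = self.delimiters
        parts: list[str] = []
        stem_tokens: list[str] = []
        in_stem = False
        for tid in ids:
            if tid == EOT:
                break
            if tid == PAD:
                continue
            if tid == U_A:
                parts.append(u_a)
            elif tid == U_B:
                parts.append(u_b)
                in_stem = True
            else:
                token = self.id_to_token.get(int(tid), "<unk>")
                if in_stem:
                    stem_tokens.append(token)
                else:
                    parts.append(token)
        return "".join(parts) + self._join_stem(stem_tokens)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        lines = [
            f"# scheme={self.scheme} u_A={self.delimiters[0]} u_B={self.delimiters[1]}",
            f"# reserved: <pad>={PAD} <unk>={UNK} <eot>={EOT} u_A={U_A} u_B={U_B}",
            f"# labels: {';'.join(sorted(self.label_set))}",
            "token\tid",
        ]
        for token, tid in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
            lines.append(f"{token}\t{tid}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocab":
        text = Path(path).read_text(encoding="utf-8").splitlines()
        meta = dict(
            kv.split("=", 1) for kv in text[0].lstrip("# ").split() if "=" in kv
        )
        labels = text[2].partition(":")[2].strip()
        label_set = frozenset(x for x in labels.split(";") if x)
        token_to_id: dict[str, int] = {}
        for line in text[4:]:
            if not line.strip():
                continue
            token, _, tid = line.rpartition("\t")
            token_to_id[token] = int(tid)
        return cls(
            token_to_id=token_to_id,
            id_to_token={v: k for k, v in token_to_id.items()},
            delimiters=(meta["u_A"], meta["u_B"]),
            scheme=meta.get("scheme", "word"),
            label_set=label_set,
        )


def fit_vocab(
    corpus: Sequence[EncodedExample],
    scheme: str = "word",
    label_set: Iterable[str] | None = None,
    delimiters: Sequence[str] = DEFAULT_DELIMITERS,
) -> Vocab:
    """Build a vocabulary from encoded examples.

    Every construct label in ``label_set`` (default: all labels occurring in
    the corpus) is registered as one token, ahead of stem tokenization.
    """
    if not corpus:
        raise CodecError("cannot fit a vocabulary on an empty corpus")
    if scheme not in ("word", "char"):
        raise CodecError(f"unknown tokenization scheme {scheme!r}")
    u_a, u_b = _check_delims(delimiters)
    if label_set is None:
        label_set = [lab for ex in corpus for lab in ex.labels]
    labels = list(dict.fromkeys(label_set))  # order-preserving unique

    token_to_id: dict[str, int] = dict(RESERVED_TOKENS)
    token_to_id[u_a] = U_A
    token_to_id[u_b] = U_B
    next_id = N_RESERVED_FIXED
    for lab in labels:
        if lab not in token_to_id:
            token_to_id[lab] = next_id
            next_id += 1
    vocab = Vocab(
        token_to_id=token_to_id,
        id_to_token={},
        delimiters=(u_a, u_b),
        scheme=scheme,
        label_set=frozenset(labels),
    )
    for ex in corpus:
        for tok in vocab._split_stem(ex.stem):
            if tok not in token_to_id:
                token_to_id[tok] = next_id
                next_id += 1
    vocab.id_to_token = {v: k for k, v in token_to_id.items()}
    return vocab
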