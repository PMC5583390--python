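"""Backbone fragmentation into canonical monomer n-grams.

An NRP backbone — the ordered chain of monomers assembled by consecutive
NRPS modules — is cut into adjacent fragments.  Pairs (bigrams) are the
default unit of all downstream analysis: a fragment's identity survives
mass-spectrometric or NMR observation regardless of which end of the
molecule it came from, so fragments are normalized by sorting their member
tokens alphabetically and joining with ``.`` (``val`` + ``ala`` →
``ala.val``).  Fragments from predicted core structures are called POPs
(pairs of predictions); fragments from known compounds are PECs (pairs of
existent compounds).  Unigrams and trigrams are supported for sensitivity
analysis.

Fragmentation is linear: no wrap-around fragment joins the terminal
monomer back to the start, even for backbones ending in a cyclized
residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

from .exceptions import ConfigError
from .monomer import Monomer

SOURCE_PREDICTED = "predicted"
SOURCE_KNOWN = "known_compound"

_VALID_NGRAM_SIZES = (1, 2, 3)

TokenLike = Union[Monomer, str]


def _token(x: TokenLike) -> str:
    return x.token if isinstance(x, Monomer) else str(x)


@dataclass(frozen=True)
class Pair:
    """A canonical two-monomer fragment; ``left <= right`` lexicographically."""

    left: str
    right: str

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError(f"Pair tokens must be sorted: {self.left!r} > {self.right!r}")

    @property
    def key(self) -> str:
        return f"{self.left}.{self.right}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


def canonical_pair(a: TokenLike, b: TokenLike) -> Pair:
    """Alphabetically normalized pair of two monomers; symmetric in arguments."""
    left, right = sorted((_token(a), _token(b)))
    return Pair(left, right)


def canonical_fragment(tokens: Iterable[TokenLike]) -> str:
    """Canonical key for an n-gram: member tokens sorted and dot-joined."""
    return ".".join(sorted(_token(t) for t in tokens))


def pair_tokens(key: str) -> tuple[str, ...]:
    """Member tokens of a canonical fragment key."""
    return tuple(key.split("."))


@dataclass
class Backbone:
    """Ordered monomer chain of a compound or predicted core structure."""

    monomers: list[Monomer]
    source_kind: str = SOURCE_PREDICTED
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.monomers)

    @property
    def tokens(self) -> list[str]:
        return [m.token for m in self.monomers]


@dataclass
class PairMultiset:
    """Fragments of one backbone with multiplicities.

    ``counts`` maps canonical fragment keys to positive multiplicities;
    the unique-set view (:meth:`support`) feeds binary matrices and the
    Jaccard index, while multiplicities feed distribution percentages.
    ``too_short`` flags a backbone shorter than the n-gram size.
    """

    counts: dict[str, int] = field(default_factory=dict)
    origin: str = ""
    n_gram_size: int = 2
    too_short: bool = False

    def support(self) -> frozenset[str]:
        return frozenset(self.counts)

    def total(self) -> int:
        return sum(self.counts.values())

    def __bool__(self) -> bool:
        return bool(self.counts)


def fragment_backbone(b: Backbone, n_gram_size: int = 2) -> PairMultiset:
    """Cut a backbone into adjacent canonical n-grams with multiplicities.

    A backbone of length ``L`` yields exactly ``L − n + 1`` fragments for
    n-gram size ``n`` (counting multiplicity); a backbone shorter than
    ``n`` yields an empty multiset flagged ``too_short``.
    """
    if n_gram_size not in _VALID_NGRAM_SIZES:
        raise ConfigError(
            f"n_gram_size must be one of {_VALID_NGRAM_SIZES}, got {n_gram_size}"
        )
    tokens = b.tokens
    if len(tokens) < n_gram_size:
        return PairMultiset(
            counts={}, origin=b.source_id, n_gram_size=n_gram_size, too_short=True
        )
    counts: dict[str, int] = {}
    for i in range(len(tokens) - n_gram_size + 1):
        key = canonical_fragment(tokens[i : i + n_gram_size])
        counts[key] = counts.get(key, 0) + 1
    return PairMultiset(counts=counts, origin=b.source_id, n_gram_size=n_gram_size)


def unique_pairs(ms: PairMultiset) -> frozenset[str]:
    """Support of the multiset: each fragment once, multiplicities dropped."""
    return ms.support()


def write_multisets_tsv(multisets: Iterable[PairMultiset], path) -> None:
    """Serialize fragment multisets as TSV with columns origin, pair_key, count."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("origin\tpair_key\tcount\n")
        for ms in multisets:
            for key in sorted(ms.counts):
                fh.write(f"{ms.origin}\t{key}\t{ms.counts[key]}\n")
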