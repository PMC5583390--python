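"""Monomer vocabulary: normalization, predictor consensus, polyketide classes.

The building blocks of nonribosomal peptides (NRPs) are amino acids —
proteinogenic or otherwise (ornithine, 2,4-diaminobutyric acid, ...) — and,
in hybrid NRPS–PKS products, polyketide extender units such as malonyl
(``mal``) or hydroxymalonyl (``ohmal``).  Monomer calls for each NRPS module
come from three adenylation-domain specificity predictors (NRPSpredictor2,
the Stachelhaus code, Minowa).  A module is trusted only when the predictors
agree; discordant modules are recorded as the unresolved token ``nrp``,
meaning the side chain could not be assigned.

Raw tokens may carry modification annotations in parentheses — e.g.
``Orn(cyclic)`` for a cyclized C-terminal ornithine or ``Thr(mod)`` for a
post-translationally modified threonine.  Tags are stripped into
:attr:`Monomer.modifications` and never participate in monomer equality:
pair analysis compares bare building blocks.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional

from .exceptions import ConfigError, InputError

#: The three adenylation-domain specificity predictors, in canonical order.
PREDICTORS = ("NRPSpredictor2", "Stachelhaus", "Minowa")

#: Token recording predictor discordance ("side chain not assigned").
NRP_TOKEN = "nrp"

KIND_AMINO_ACID = "amino_acid"
KIND_POLYKETIDE = "polyketide"
KIND_UNRESOLVED = "unresolved"

_PAREN_RE = re.compile(r"\(([^()]*)\)")


def _read_tsv_rows(path) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].lstrip().startswith("#"):
                continue
            rows.append([cell.strip() for cell in row])
    return rows


def _data_path(name: str):
    return resources.files("nrpairs.data").joinpath(name)


@lru_cache(maxsize=1)
def default_synonyms() -> Mapping[str, str]:
    """Bundled raw→canonical spelling table (editable TSV in package data)."""
    return load_synonyms(_data_path("synonyms.tsv"))


def load_synonyms(path) -> Mapping[str, str]:
    """Read a two-column raw→canonical TSV; raw keys are matched lowercase."""
    table: dict[str, str] = {}
    for lineno, row in enumerate(_read_tsv_rows(path), 1):
        if len(row) < 2:
            raise InputError(f"{path}: synonym row {lineno} needs two columns, got {row!r}")
        table[row[0].lower()] = row[1].lower()
    return table


@dataclass(frozen=True)
class Monomer:
    """A single normalized building block.

    Equality and hashing use ``token`` only: two monomers with the same
    token but different modification tags compare equal, because the pair
    fingerprint deliberately ignores tailoring.
    """

    token: str
    kind: str = KIND_AMINO_ACID
    modifications: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.token:
            raise InputError("monomer token must be nonempty")
        if any(ch.isspace() for ch in self.token) or "." in self.token:
            raise InputError(
                f"monomer token {self.token!r} may not contain whitespace or '.'"
            )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


def _kind_of(token: str) -> str:
    if token == NRP_TOKEN:
        return KIND_UNRESOLVED
    if token in PkClassTable.default().members:
        return KIND_POLYKETIDE
    return KIND_AMINO_ACID


def normalize_monomer(
    raw_token: str, synonyms: Optional[Mapping[str, str]] = None
) -> Monomer:
    """Turn a raw predictor/compound token into a canonical :class:`Monomer`.

    Parenthesized annotations are stripped into modification tags (``+``
    separates stacked tags, as in ``pk(NH2+ohmal)``), the core is lowercased,
    and spelling variants are resolved through the synonym table.

    >>> normalize_monomer("Orn(cyclic)").token
    'orn'
    >>> normalize_monomer("Orn(cyclic)").modifications
    ('cyclic',)
    """
    if raw_token is None or not str(raw_token).strip():
        raise InputError("empty monomer token")
    text = str(raw_token).strip()
    mods: list[str] = []

    def _grab(match: re.Match) -> str:
        mods.extend(p.strip() for p in match.group(1).split("+") if p.strip())
        return ""

    core = _PAREN_RE.sub(_grab, text).strip().strip("_").strip()
    core = core.lower()
    table = default_synonyms() if synonyms is None else synonyms
    core = table.get(core, core)
    if not core:
        raise InputError(f"token {raw_token!r} is empty after stripping annotations")
    return Monomer(token=core, kind=_kind_of(core), modifications=tuple(mods))


UNRESOLVED = Monomer(NRP_TOKEN, KIND_UNRESOLVED)


@dataclass(frozen=True)
class PredictorCalls:
    """Raw per-module monomer calls from the three predictors.

    ``calls`` maps each predictor name in :data:`PREDICTORS` to its raw
    token, or ``None`` when the predictor produced no call.  All three
    slots must be present (an absent call is an explicit ``None``, never a
    missing key or empty string).
    """

    calls: Mapping[str, Optional[str]]

    def __post_init__(self) -> None:
        got = set(self.calls)
        if got != set(PREDICTORS):
            unknown = sorted(got - set(PREDICTORS))
            missing = sorted(set(PREDICTORS) - got)
            raise InputError(
                f"predictor calls must use exactly {PREDICTORS}; "
                f"unknown={unknown} missing={missing}"
            )
        for name, value in self.calls.items():
            if value is not None and not str(value).strip():
                raise InputError(
                    f"predictor {name}: absent calls must be None, not an empty string"
                )


CONSENSUS_POLICIES = ("strict", "majority")


def consensus_call(
    calls: PredictorCalls,
    policy: str = "strict",
    synonyms: Optional[Mapping[str, str]] = None,
) -> Monomer:
    """Collapse three predictor calls into one monomer.

    Under the default ``strict`` policy all three predictors must agree
    (after normalization) for the monomer to be accepted; any discordance —
    including an absent call — yields the unresolved token ``nrp``.  The
    ``majority`` policy accepts a 2-of-3 agreement instead.
    """
    if policy not in CONSENSUS_POLICIES:
        raise ConfigError(f"unknown consensus policy {policy!r}; use one of {CONSENSUS_POLICIES}")
    normalized = [
        normalize_monomer(calls.calls[name], synonyms)
        if calls.calls[name] is not None
        else None
        for name in PREDICTORS
    ]
    tokens = [m.token if m is not None else None for m in normalized]
    if policy == "strict":
        if None not in tokens and len(set(tokens)) == 1:
            return normalized[0]
        return UNRESOLVED
    counts: dict[str, int] = {}
    for tok in tokens:
        if tok is not None:
            counts[tok] = counts.get(tok, 0) + 1
    for tok, n in counts.items():
        if n >= 2:
            return next(m for m in normalized if m is not None and m.token == tok)
    return UNRESOLVED


@dataclass(frozen=True)
class PkClassTable:
    """Tokens pooled into one polyketide class for pair comparison.

    Hybrid NRPS–PKS clusters intersperse polyketide extender units with
    amino acids.  Known-compound backbones often record the generic unit
    ``pk`` while predictions name the specific extender (``ohmal``,
    ``mal``, ...); pooling them makes the two comparable.
    """

    members: frozenset[str] = frozenset({"pk", "mal", "mmal", "ohmal", "emal", "mxmal"})
    class_token: str = "pk"

    def __post_init__(self) -> None:
        if self.class_token not in self.members:
            raise ConfigError(
                f"class token {self.class_token!r} must be a member of {sorted(self.members)}"
            )

    def __contains__(self, token: str) -> bool:
        return str(token).lower() in self.members

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "PkClassTable":
        return cls.from_tsv(_data_path("pk_class.tsv"))

    @classmethod
    def from_tsv(cls, path) -> "PkClassTable":
        """Read a one-column TSV; the first row is the class token."""
        rows = _read_tsv_rows(path)
        if not rows:
            raise InputError(f"{path}: polyketide class table is empty")
        tokens = [row[0].lower() for row in rows]
        return cls(members=frozenset(tokens), class_token=tokens[0])


def pk_classify(m, table: Optional[PkClassTable] = None) -> str:
    """Map a monomer (or bare token) to its comparison token.

    Members of the polyketide class collapse onto the class token ``pk``;
    every other token passes through unchanged.
    """
    table = table or PkClassTable.default()
    token = m.token if isinstance(m, Monomer) else str(m).lower()
    return table.class_token if token in table else token
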