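"""Known-compound library: ordered monomer backbones of characterized NRPs.

Each entry pairs a compound name with its MIBiG accession and backbone,
transcribed monomer by monomer in biosynthetic order with modification
annotations in parentheses.  The bundled default library ships
Delftibactin — the metallophore of *Delftia acidovorans* (MIBiG
BGC0000984), a classic hybrid NRPS–PKS product — whose nine-unit backbone
serves as the validation template throughout the package.  Further
compounds (Malleobactin, tridecaptins, ...) are added by the user in the
same TSV format.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional

from .exceptions import InputError
from .fragmentation import Backbone, PairMultiset, SOURCE_KNOWN, fragment_backbone
from .monomer import Monomer, normalize_monomer

_MIBIG_RE = re.compile(r"^BGC\d{7}(_c\d+)?$")
_COLUMNS = ("name", "mibig_id", "backbone", "citation")


@dataclass
class CompoundEntry:
    """One known nonribosomal peptide with its ordered backbone."""

    name: str
    mibig_id: str
    backbone: Backbone
    citation: str = ""

    def __post_init__(self) -> None:
        if self.mibig_id and not _MIBIG_RE.match(self.mibig_id):
            raise InputError(
                f"compound {self.name!r}: MIBiG id {self.mibig_id!r} does not match BGC#######"
            )


def parse_backbone(
    text: str, source_id: str = "", synonyms: Optional[Mapping[str, str]] = None
) -> Backbone:
    """Parse a comma-separated raw-token backbone, e.g. ``Asp,Thr(mod),Gly``."""
    raw_tokens = [t for t in (p.strip() for p in text.split(",")) if t]
    if not raw_tokens:
        raise InputError(f"compound {source_id!r}: empty backbone")
    monomers = [normalize_monomer(t, synonyms) for t in raw_tokens]
    return Backbone(monomers=monomers, source_kind=SOURCE_KNOWN, source_id=source_id)


def default_library_path():
    return resources.files("nrpairs.data").joinpath("compounds.tsv")


def load_compound_library(
    path=None, synonyms: Optional[Mapping[str, str]] = None
) -> list[CompoundEntry]:
    """Load a compound library TSV (columns name, mibig_id, backbone, citation).

    Backbones are normalized on load.  Duplicate compound names are an
    error; malformed tokens are reported with their line number.
    """
    path = default_library_path() if path is None else path
    entries: list[CompoundEntry] = []
    seen: dict[str, int] = {}
    duplicates: list[str] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: Optional[list[str]] = None
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in row]
                if tuple(header[: len(_COLUMNS)]) != _COLUMNS:
                    raise InputError(
                        f"{path}: expected header columns {_COLUMNS}, got {header}"
                    )
                continue
            row += [""] * (len(_COLUMNS) - len(row))
            name, mibig_id, backbone_text, citation = (c.strip() for c in row[:4])
            if not name:
                raise InputError(f"{path}:{lineno}: compound name is empty")
            if name in seen:
                duplicates.append(name)
                continue
            seen[name] = lineno
            try:
                backbone = parse_backbone(backbone_text, source_id=name, synonyms=synonyms)
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            entries.append(
                CompoundEntry(name=name, mibig_id=mibig_id, backbone=backbone, citation=citation)
            )
    if duplicates:
        raise InputError(f"{path}: duplicate compound names: {sorted(set(duplicates))}")
    return entries


def write_compound_library(entries: Iterable[CompoundEntry], path) -> None:
    """Write entries back to the library TSV format (modifications preserved)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for e in entries:
            tokens = []
            for m in e.backbone.monomers:
                tok = m.token
                if m.modifications:
                    tok += "(" + "+".join(m.modifications) + ")"
                tokens.append(tok)
            fh.write(f"{e.name}\t{e.mibig_id}\t{','.join(tokens)}\t{e.citation}\n")


def get_compound(entries: Iterable[CompoundEntry], name: str) -> CompoundEntry:
    for e in entries:
        if e.name == name:
            return e
    raise InputError(f"compound {name!r} not found in library")


def pecs_for(c: CompoundEntry, n_gram_size: int = 2) -> PairMultiset:
    """Fragment a known compound's backbone into its PEC multiset."""
    return fragment_backbone(c.backbone, n_gram_size=n_gram_size)


def make_compound(
    name: str,
    tokens: Iterable[str],
    mibig_id: str = "",
    citation: str = "",
    synonyms: Optional[Mapping[str, str]] = None,
) -> CompoundEntry:
    """Convenience constructor from raw backbone tokens."""
    monomers = [normalize_monomer(t, synonyms) for t in tokens]
    return CompoundEntry(
        name=name,
        mibig_id=mibig_id,
        backbone=Backbone(monomers=monomers, source_kind=SOURCE_KNOWN, source_id=name),
        citation=citation,
    )
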