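"""Reading, validating and writing BGC prediction records.

A :class:`ClusterRecord` captures one biosynthetic gene cluster as an
antiSMASH-era genome-mining run reports it: the organism and genome
accession, the cluster's index and type (``NRPS``, ``NRPS-T1PKS``, ...),
the per-module monomer calls of the three specificity predictors, and —
when the cluster resembles a characterized one — the most similar known
cluster (compound name, MIBiG id, percentage of homologous genes).

The canonical on-disk form is a versioned JSON array (schema shipped in
package data as ``record_schema.json``); an equivalent flat TSV is read
and written for spreadsheet workflows.  Records from draft genomes with
no prediction are retained but inert: they contribute no pairs, so the
dataset is naturally filtered to clusters that produced POPs.
"""

from __future__ import annotations

import json
import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .exceptions import ConfigError, InputError
from .fragmentation import Backbone, PairMultiset, SOURCE_PREDICTED, fragment_backbone
from .monomer import PREDICTORS, PredictorCalls, consensus_call, normalize_monomer

SCHEMA_VERSION = 1

_TSV_COLUMNS = (
    "organism",
    "genome_accession",
    "cluster_index",
    "cluster_type",
    "modules",
    "known_compound",
    "known_mibig",
    "identity_percent",
)
_ABSENT = "-"  # absent predictor call in the TSV module encoding


@dataclass(frozen=True)
class KnownMatch:
    """Most similar known cluster annotation (from MIBiG), carried verbatim."""

    compound_name: str
    mibig_id: str = ""
    identity_percent: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= float(self.identity_percent) <= 100.0:
            raise InputError(
                f"identity_percent {self.identity_percent!r} outside [0, 100]"
            )


@dataclass
class ClusterRecord:
    """One BGC with its per-module predictor calls."""

    organism: str
    cluster_index: int
    genome_accession: str = ""
    cluster_type: str = "NRPS"
    modules: list[PredictorCalls] = field(default_factory=list)
    known_match: Optional[KnownMatch] = None

    def __post_init__(self) -> None:
        if int(self.cluster_index) < 1:
            raise InputError(f"cluster_index must be >= 1, got {self.cluster_index}")
        if not (self.organism or self.genome_accession):
            raise InputError("record needs an organism name or a genome accession")

    @property
    def cluster_key(self) -> str:
        base = self.organism or self.genome_accession
        return f"{base}-C{self.cluster_index}"

    @property
    def has_predictions(self) -> bool:
        return bool(self.modules)


@dataclass
class RecordSet:
    """A validated collection of cluster records with unique keys."""

    records: list[ClusterRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.cluster_key in seen:
                raise InputError(f"duplicate cluster key {r.cluster_key!r}")
            seen.add(r.cluster_key)

    def __len__(self) -> int:
        return len(self.records)

    def by_key(self) -> dict[str, ClusterRecord]:
        return {r.cluster_key: r for r in self.records}

    def organisms(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            name = r.organism or r.genome_accession
            if name not in out:
                out.append(name)
        return out


# ---------------------------------------------------------------------------
# JSON reading / writing


def _record_from_obj(obj: Mapping, pos: str) -> ClusterRecord:
    if not isinstance(obj, Mapping):
        raise InputError(f"{pos}: record must be an object, got {type(obj).__name__}")
    for req in ("organism", "cluster_index"):
        if req not in obj and not (req == "organism" and obj.get("genome_accession")):
            raise InputError(f"{pos}: missing required field {req!r}")
    modules_raw = obj.get("modules", [])
    if not isinstance(modules_raw, list):
        raise InputError(f"{pos}: 'modules' must be a list")
    modules: list[PredictorCalls] = []
    for i, mod in enumerate(modules_raw, 1):
        if not isinstance(mod, Mapping):
            raise InputError(f"{pos} module {i}: must be an object of predictor calls")
        try:
            modules.append(PredictorCalls(calls=dict(mod)))
        except InputError as exc:
            raise InputError(f"{pos} module {i}: {exc}") from exc
    km_raw = obj.get("known_match")
    known = None
    if km_raw is not None:
        if not isinstance(km_raw, Mapping) or "compound_name" not in km_raw:
            raise InputError(f"{pos}: known_match must carry a compound_name")
        try:
            known = KnownMatch(
                compound_name=str(km_raw["compound_name"]),
                mibig_id=str(km_raw.get("mibig_id", "")),
                identity_percent=float(km_raw.get("identity_percent", 0.0)),
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"{pos}: {exc}") from exc
    try:
        return ClusterRecord(
            organism=str(obj.get("organism", "")),
            genome_accession=str(obj.get("genome_accession", "")),
            cluster_index=int(obj["cluster_index"]),
            cluster_type=str(obj.get("cluster_type", "NRPS")),
            modules=modules,
            known_match=known,
        )
    except (InputError, ValueError) as exc:
        raise InputError(f"{pos}: {exc}") from exc


def read_cluster_records(path) -> RecordSet:
    """Read a record file (JSON array or flat TSV, chosen by extension).

    Every monomer token is normalized downstream on first use; validation
    failures name the offending record and field.
    """
    text_path = str(path)
    if text_path.endswith((".tsv", ".txt")):
        return _read_records_tsv(path)
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InputError(f"{path}: not valid JSON ({exc})") from exc
    provenance = ""
    if isinstance(data, Mapping):
        provenance = str(data.get("provenance", ""))
        data = data.get("records")
    if not isinstance(data, list):
        raise InputError(f"{path}: expected a JSON array of records")
    records = [_record_from_obj(obj, f"{path} record {i}") for i, obj in enumerate(data, 1)]
    return RecordSet(records=records, provenance=provenance)


def record_to_obj(r: ClusterRecord) -> dict:
    obj: dict = {
        "organism": r.organism,
        "genome_accession": r.genome_accession,
        "cluster_index": r.cluster_index,
        "cluster_type": r.cluster_type,
        "modules": [
            {name: pc.calls[name] for name in PREDICTORS} for pc in r.modules
        ],
        "known_match": None,
    }
    if r.known_match is not None:
        obj["known_match"] = {
            "compound_name": r.known_match.compound_name,
            "mibig_id": r.known_match.mibig_id,
            "identity_percent": r.known_match.identity_percent,
        }
    return obj


def write_cluster_records(rs: RecordSet, json_path=None, tsv_path=None) -> None:
    """Serialize a record set to JSON and/or TSV."""
    if json_path is not None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "provenance": rs.provenance,
            "records": [record_to_obj(r) for r in rs.records],
        }
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_TSV_COLUMNS)
            for r in rs.records:
                modules = ";".join(
                    "|".join(
                        pc.calls[name] if pc.calls[name] is not None else _ABSENT
                        for name in PREDICTORS
                    )
                    for pc in r.modules
                )
                km = r.known_match
                writer.writerow(
                    [
                        r.organism,
                        r.genome_accession,
                        r.cluster_index,
                        r.cluster_type,
                        modules,
                        km.compound_name if km else "",
                        km.mibig_id if km else "",
                        repr(float(km.identity_percent)) if km else "",
                    ]
                )


def _read_records_tsv(path) -> RecordSet:
    records: list[ClusterRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = tuple(c.strip() for c in row)
                if header != _TSV_COLUMNS:
                    raise InputError(f"{path}: expected columns {_TSV_COLUMNS}, got {header}")
                continue
            pos = f"{path}:{lineno}"
            row += [""] * (len(_TSV_COLUMNS) - len(row))
            organism, accession, idx, ctype, modules_enc, kc, km_id, ident = row[:8]
            modules: list[PredictorCalls] = []
            if modules_enc:
                for i, enc in enumerate(modules_enc.split(";"), 1):
                    calls = enc.split("|")
                    if len(calls) != len(PREDICTORS):
                        raise InputError(
                            f"{pos} module {i}: expected {len(PREDICTORS)} calls, got {enc!r}"
                        )
                    modules.append(
                        PredictorCalls(
                            calls={
                                name: (c if c != _ABSENT else None)
                                for name, c in zip(PREDICTORS, calls)
                            }
                        )
                    )
            known = None
            if kc:
                try:
                    known = KnownMatch(
                        compound_name=kc,
                        mibig_id=km_id,
                        identity_percent=float(ident) if ident else 0.0,
                    )
                except (InputError, ValueError) as exc:
                    raise InputError(f"{pos}: {exc}") from exc
            try:
                records.append(
                    ClusterRecord(
                        organism=organism,
                        genome_accession=accession,
                        cluster_index=int(idx),
                        cluster_type=ctype,
                        modules=modules,
                        known_match=known,
                    )
                )
            except (InputError, ValueError) as exc:
                raise InputError(f"{pos}: {exc}") from exc
    return RecordSet(records=records)


# ---------------------------------------------------------------------------
# POP derivation


def consensus_backbone(
    r: ClusterRecord, policy: str = "strict", synonyms=None
) -> Backbone:
    """Apply the consensus rule per module to get the predicted backbone."""
    monomers = [consensus_call(pc, policy=policy, synonyms=synonyms) for pc in r.modules]
    return Backbone(monomers=monomers, source_kind=SOURCE_PREDICTED, source_id=r.cluster_key)


def pops_for(
    r: ClusterRecord,
    policy: str = "strict",
    n_gram_size: int = 2,
    synonyms=None,
) -> PairMultiset:
    """Derive a record's POP multiset: consensus calls, then fragmentation.

    Records without predictions yield an empty multiset (flagged
    ``too_short``), keeping draft-genome entries inert.
    """
    if not r.modules:
        return PairMultiset(counts={}, origin=r.cluster_key, n_gram_size=n_gram_size, too_short=True)
    return fragment_backbone(
        consensus_backbone(r, policy=policy, synonyms=synonyms), n_gram_size=n_gram_size
    )
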