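"""End-to-end orchestration: ingest → pairs → scores → matrices → networks.

:func:`run_pipeline` executes every analysis stage on one record file and
writes all artifacts into an output directory together with a run
manifest (inputs, options, package version, SHA-256 checksum of every
output) sufficient to verify a byte-identical re-run.  Per-stage record
counts are logged to standard error so the natural filtering of the
dataset (clusters without predictions contribute nothing) stays
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .exceptions import InputError
from .fragmentation import write_multisets_tsv
from .ingest import read_cluster_records, pops_for
from .library import load_compound_library
from .scoring import (
    identity_vs_correctness,
    score_cluster,
    write_score_report,
    write_score_summary,
)
from .similarity import (
    branch_distribution,
    build_binary_matrix,
    hierarchical_cluster,
    jaccard_matrix,
    pec_vs_pop_distribution,
    pop_distribution,
    read_branch_assignments,
    write_distribution_tsv,
)
from .network import build_network, write_network, write_node_attributes

logger = logging.getLogger("nrpairs")


@dataclass
class RunManifest:
    """What a pipeline run consumed and produced."""

    inputs: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    version: str = __version__
    outputs: dict = field(default_factory=dict)  # relative path -> sha256

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "inputs": self.inputs,
                    "options": self.options,
                    "version": self.version,
                    "outputs": self.outputs,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    records_path,
    out_dir,
    library_path=None,
    branches_path=None,
    policy: str = "strict",
    n_gram_size: int = 2,
    granularity: str = "cluster",
    min_edges: int = 5,
    with_multiplicity: bool = True,
) -> RunManifest:
    """Run every stage and write artifacts plus ``manifest.json`` to ``out_dir``."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s: %(message)s")
    rs = read_cluster_records(records_path)
    if not rs.records:
        raise InputError(f"{records_path}: no records to analyse")
    library = load_compound_library(library_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    pops = [pops_for(r, policy=policy, n_gram_size=n_gram_size) for r in rs.records]
    n_empty = sum(1 for ms in pops if not ms.counts)
    logger.info("ingested %d clusters (%d without POPs)", len(rs.records), n_empty)

    p = out / "pops.tsv"
    write_multisets_tsv(pops, p)
    outputs.append(p)

    names = {c.name for c in library}
    scores = [
        score_cluster(r, next(c for c in library if c.name == r.known_match.compound_name),
                      policy=policy, n_gram_size=n_gram_size)
        for r in rs.records
        if r.known_match is not None and r.known_match.compound_name in names and r.has_predictions
    ]
    logger.info("scored %d clusters against library compounds", len(scores))
    if scores:
        p = out / "score_report.tsv"
        write_score_report(scores, rs, p)
        outputs.append(p)
        p = out / "score_summary.tsv"
        write_score_summary(scores, p)
        outputs.append(p)
        table = identity_vs_correctness(scores, rs)
        p = out / "identity_vs_correctness.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.6f")
        outputs.append(p)

    bm = build_binary_matrix(rs, granularity=granularity, policy=policy, n_gram_size=n_gram_size)
    p = out / "binary_matrix.tsv"
    bm.write_tsv(p)
    outputs.append(p)
    ji = jaccard_matrix(bm)
    p = out / "jaccard_matrix.tsv"
    ji.write_tsv(p)
    outputs.append(p)
    if len(bm.instance_ids) >= 2:
        dend = hierarchical_cluster(bm)
        p = out / "dendrogram.nwk"
        p.write_text(dend.to_newick() + "\n", encoding="utf-8")
        outputs.append(p)
        p = out / "leaf_order.txt"
        p.write_text("\n".join(dend.leaf_order) + "\n", encoding="utf-8")
        outputs.append(p)

    nonempty = [ms for ms in pops if ms.counts]
    if nonempty:
        p = out / "pop_distribution.tsv"
        write_distribution_tsv(pop_distribution(nonempty, with_multiplicity), p)
        outputs.append(p)
    try:
        df = pec_vs_pop_distribution(
            rs, library, policy=policy, n_gram_size=n_gram_size,
            with_multiplicity=with_multiplicity,
        )
        p = out / "pec_vs_pop.tsv"
        write_distribution_tsv(df, p)
        outputs.append(p)
    except InputError:
        logger.info("no known matches resolve in the compound library; skipping PEC-vs-POP table")

    if branches_path is not None:
        assignments = read_branch_assignments(branches_path)
        tables = branch_distribution(
            rs, assignments, policy=policy, n_gram_size=n_gram_size,
            with_multiplicity=with_multiplicity,
        )
        for branch, table in tables.items():
            p = out / f"distribution_{branch}.tsv"
            write_distribution_tsv(table, p)
            outputs.append(p)

    for mode in ("compound", "pop"):
        g = build_network(rs, mode=mode, policy=policy, n_gram_size=n_gram_size)
        p = out / f"network_{mode}.sif"
        write_network(g, p, format="sif")
        outputs.append(p)
        p = out / f"network_{mode}.graphml"
        write_network(g, p, format="graphml")
        outputs.append(p)
        p = out / f"network_{mode}_nodes.tsv"
        write_node_attributes(g, p)
        outputs.append(p)

    manifest = RunManifest(
        inputs={
            "records": str(records_path),
            "library": str(library_path) if library_path else "bundled",
            "branches": str(branches_path) if branches_path else None,
        },
        options={
            "policy": policy,
            "n_gram_size": n_gram_size,
            "granularity": granularity,
            "min_edges": min_edges,
            "with_multiplicity": with_multiplicity,
        },
        outputs={p.name: _sha256(p) for p in outputs},
    )
    manifest.write(out / "manifest.json")
    logger.info("wrote %d artifacts to %s", len(outputs) + 1, out)
    return manifest
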