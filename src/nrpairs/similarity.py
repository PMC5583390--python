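"""Binary pair matrices, Jaccard similarity, clustering and distributions.

Cross-species comparison treats each instance (a gene cluster, or an
organism pooling its clusters) as a binary fingerprint over the observed
pair vocabulary: 1 where the instance's POP set contains the pair, 0
where it does not.  Similarity between instances is the Jaccard index
JI = |A∩B| / |A∪B| of their POP sets, in [0, 1]; instances are grouped by
agglomerative clustering of the binary rows (Euclidean distance, average
linkage).  Distribution tables report each pair's share of a group's
fragments — globally, per compound cohort, or per dendrogram branch —
with multiplicities counted by default (a fragment occurring twice in a
backbone contributes twice).

The unresolved pair ``nrp.nrp`` is retained in matrices and
distributions (its prevalence signals clusters whose modules could not
be called) even though it scores zero points in compound matching.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import distance

from .exceptions import ConfigError, InputError
from .fragmentation import PairMultiset
from .ingest import RecordSet, pops_for
from .library import CompoundEntry, get_compound, pecs_for

GRANULARITIES = ("cluster", "organism")

#: Label of the global (whole-dataset) distribution emitted alongside branches.
GLOBAL_BRANCH = "Branch_0"


@dataclass
class BinaryMatrix:
    """Instances × pair-attributes presence/absence matrix."""

    instance_ids: list[str]
    attribute_ids: list[str]
    values: np.ndarray  # shape (n_instances, n_attributes), dtype int8
    empty_instances: list[str] = field(default_factory=list)

    def row_support(self, i: int) -> frozenset[str]:
        row = self.values[i]
        return frozenset(a for a, v in zip(self.attribute_ids, row) if v)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.instance_ids, columns=self.attribute_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="instance")


@dataclass
class JIMatrix:
    """Symmetric pairwise Jaccard-index matrix over instances."""

    ids: list[str]
    values: np.ndarray
    empty_instances: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="instance", float_format="%.6f")


def build_binary_matrix(
    rs: RecordSet,
    granularity: str = "cluster",
    policy: str = "strict",
    n_gram_size: int = 2,
) -> BinaryMatrix:
    """Presence/absence matrix of pairs per instance.

    At the default ``cluster`` granularity each gene cluster is one row
    (keys like ``B. caribensis-C9``); at ``organism`` granularity every
    organism's clusters are pooled into one row by set union.  Columns are
    all observed pairs in alphabetical order; rows keep first-appearance
    order.  Instances with no POPs give all-zero rows, listed in
    ``empty_instances``.
    """
    if granularity not in GRANULARITIES:
        raise ConfigError(f"granularity must be one of {GRANULARITIES}, got {granularity!r}")
    supports: dict[str, set[str]] = {}
    order: list[str] = []
    for r in rs.records:
        key = r.cluster_key if granularity == "cluster" else (r.organism or r.genome_accession)
        if key not in supports:
            supports[key] = set()
            order.append(key)
        supports[key] |= pops_for(r, policy=policy, n_gram_size=n_gram_size).support()
    attributes = sorted(set().union(*supports.values())) if supports else []
    values = np.zeros((len(order), len(attributes)), dtype=np.int8)
    col = {a: j for j, a in enumerate(attributes)}
    for i, key in enumerate(order):
        for a in supports[key]:
            values[i, col[a]] = 1
    empty = [k for k in order if not supports[k]]
    return BinaryMatrix(
        instance_ids=order, attribute_ids=attributes, values=values, empty_instances=empty
    )


def jaccard_index(a: Iterable[str], b: Iterable[str]) -> float:
    """JI = |A∩B| / |A∪B|; defined as 0.0 when both sets are empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def jaccard_matrix(m: BinaryMatrix) -> JIMatrix:
    """Pairwise Jaccard index over the rows of a binary matrix."""
    if not m.instance_ids:
        raise InputError("cannot compute a Jaccard matrix for an empty binary matrix")
    x = m.values.astype(np.int64)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        ji = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return JIMatrix(ids=list(m.instance_ids), values=ji, empty_instances=list(m.empty_instances))


@dataclass
class Dendrogram:
    """Average-linkage merge tree over binary-matrix rows."""

    ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix (n-1, 4)
    leaf_order: list[str]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Serialize the merge tree as Newick with branch lengths.

        A node's branch length is the difference between its parent's and
        its own merge height; leaf names have Newick metacharacters
        replaced by ``_``.
        """
        tree = hierarchy.to_tree(self.linkage)

        def clean(name: str) -> str:
            for ch in " (),:;'\t\n":
                name = name.replace(ch, "_")
            return name

        def walk(node, parent_dist: float) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{clean(self.ids[node.id])}:{length:.6f}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(m: BinaryMatrix) -> Dendrogram:
    """Agglomerative clustering of instances: Euclidean distance, average linkage.

    Ties are broken deterministically by input order (SciPy's convention).
    """
    if len(m.instance_ids) < 2:
        raise InputError("hierarchical clustering needs at least two instances")
    condensed = distance.pdist(m.values.astype(float), metric="euclidean")
    z = hierarchy.linkage(condensed, method="average")
    order = [m.instance_ids[i] for i in hierarchy.leaves_list(z)]
    return Dendrogram(ids=list(m.instance_ids), linkage=z, leaf_order=order)


# ---------------------------------------------------------------------------
# Distribution tables


def pop_distribution(
    group: Iterable[PairMultiset], with_multiplicity: bool = True
) -> pd.DataFrame:
    """Share of each pair within a group of fragment multisets.

    ``percent`` = 100 × count / total over the whole group; with
    multiplicities counted by default, so a pair occurring twice in one
    backbone contributes two counts.  Sorted by count descending, then
    pair key.
    """
    group = list(group)
    if not group:
        raise InputError("pop_distribution needs a nonempty group of multisets")
    counter: Counter[str] = Counter()
    for ms in group:
        for key, n in ms.counts.items():
            counter[key] += n if with_multiplicity else 1
    total = sum(counter.values())
    if total == 0:
        raise InputError("pop_distribution: group contains no fragments")
    rows = [
        {"pair": key, "count": n, "percent": 100.0 * n / total}
        for key, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["pair", "count", "percent"])


def pec_vs_pop_distribution(
    rs: RecordSet,
    library: list[CompoundEntry],
    policy: str = "strict",
    n_gram_size: int = 2,
    with_multiplicity: bool = True,
) -> pd.DataFrame:
    """Side-by-side pair distributions of known compounds and predictions.

    Every record whose known match resolves in the compound library
    contributes its compound's PEC multiset to the observed column and its
    own POP multiset to the predicted column.  Records with unresolvable
    compound names are excluded and listed in ``attrs['excluded']``.
    Returns a table (pair, pec_percent, pop_percent) over the union
    vocabulary, sorted by pair.
    """
    pec_sets: list[PairMultiset] = []
    pop_sets: list[PairMultiset] = []
    excluded: list[str] = []
    names = {c.name: c for c in library}
    for r in rs.records:
        if r.known_match is None or not r.has_predictions:
            continue
        compound = names.get(r.known_match.compound_name)
        if compound is None:
            excluded.append(r.cluster_key)
            continue
        pec_sets.append(pecs_for(compound, n_gram_size=n_gram_size))
        pop_sets.append(pops_for(r, policy=policy, n_gram_size=n_gram_size))
    if not pec_sets:
        raise InputError("no record's known match resolves in the compound library")
    pec_dist = pop_distribution(pec_sets, with_multiplicity).set_index("pair")["percent"]
    pop_dist = pop_distribution(pop_sets, with_multiplicity).set_index("pair")["percent"]
    vocab = sorted(set(pec_dist.index) | set(pop_dist.index))
    df = pd.DataFrame(
        {
            "pair": vocab,
            "pec_percent": [float(pec_dist.get(p, 0.0)) for p in vocab],
            "pop_percent": [float(pop_dist.get(p, 0.0)) for p in vocab],
        }
    )
    df.attrs["excluded"] = excluded
    return df


def read_branch_assignments(path) -> dict[str, str]:
    """Two-column TSV cluster_key → branch label."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if row and row[0].strip() == "cluster_key":
                continue
            if len(row) < 2:
                raise InputError(f"{path}:{lineno}: expected cluster_key<TAB>branch")
            mapping[row[0].strip()] = row[1].strip()
    return mapping


def branch_distribution(
    rs: RecordSet,
    assignments: Mapping[str, str],
    policy: str = "strict",
    n_gram_size: int = 2,
    with_multiplicity: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-branch pair distributions plus the global one under ``Branch_0``.

    Each assigned cluster's POP multiset is pooled into its branch's
    table; branches whose clusters yield no fragments get an empty,
    flagged table (``attrs['empty']``).
    """
    by_key = rs.by_key()
    unknown = sorted(k for k in assignments if k not in by_key)
    if unknown:
        raise InputError(f"branch assignment refers to unknown cluster keys: {unknown}")
    if not assignments:
        raise InputError("branch assignment covers no records")
    groups: dict[str, list[PairMultiset]] = {}
    all_sets: list[PairMultiset] = []
    for key, branch in assignments.items():
        ms = pops_for(by_key[key], policy=policy, n_gram_size=n_gram_size)
        groups.setdefault(branch, []).append(ms)
        all_sets.append(ms)
    out: dict[str, pd.DataFrame] = {}
    out[GLOBAL_BRANCH] = pop_distribution(all_sets, with_multiplicity)
    for branch in sorted(groups):
        members = groups[branch]
        if not any(ms.counts for ms in members):
            empty = pd.DataFrame(columns=["pair", "count", "percent"])
            empty.attrs["empty"] = True
            out[branch] = empty
            continue
        out[branch] = pop_distribution(members, with_multiplicity)
    return out


def write_distribution_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
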