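"""The 1 / 0.5 / 0 point system comparing predictions with known compounds.

Each POP of a predicted core structure is scored against the PEC set of
the compound its gene cluster most resembles:

* **1 point (exact)** — the POP equals a PEC after both sides' polyketide
  tokens are pooled onto the class token ``pk`` (so a predicted
  ``ohmal.nrp`` can meet the compound's generic ``asp.pk``).
* **0.5 points (partial_nrp)** — exactly one member of the POP is the
  unresolved token ``nrp`` and the other member occurs somewhere in the
  compound's PECs: half of the fragment is confirmed, the other half was
  out of consensus.
* **0 points (none)** — everything else: ``nrp.nrp``, pairs of tokens the
  compound never joins adjacently, and tokens foreign to the compound.

PECs are matched as types, not consumed slots: a single PEC may confirm
several POPs, mirroring how a duplicated fragment in a backbone counts as
one pattern.  Per cluster the points are summed and divided by the number
of POPs scored, giving the fraction of correct prediction fragments that
is compared against the cluster's gene-level homology percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .fragmentation import Pair, PairMultiset, canonical_fragment, pair_tokens
from .library import CompoundEntry, pecs_for
from .ingest import ClusterRecord, RecordSet, pops_for
from .monomer import NRP_TOKEN, PkClassTable, pk_classify

MATCH_EXACT = "exact"
MATCH_PARTIAL = "partial_nrp"
MATCH_NONE = "none"

_POINTS = {MATCH_EXACT: 1.0, MATCH_PARTIAL: 0.5, MATCH_NONE: 0.0}


@dataclass(frozen=True)
class MatchResult:
    pop: str
    points: float
    match_kind: str
    matched_pec: Optional[str] = None


@dataclass
class ClusterScore:
    """Per-cluster aggregate of POP match points."""

    cluster_key: str
    compound: str
    results: list[MatchResult] = field(default_factory=list)
    no_pops: bool = False

    @property
    def total_points(self) -> float:
        return sum(r.points for r in self.results)

    @property
    def n_pops(self) -> int:
        return len(self.results)

    @property
    def fraction_correct(self) -> float:
        return self.total_points / self.n_pops if self.n_pops else 0.0


def _key_of(pop: Union[str, Pair]) -> str:
    return pop.key if isinstance(pop, Pair) else str(pop)


def _map_key(key: str, table: PkClassTable) -> str:
    return canonical_fragment(pk_classify(t, table) for t in pair_tokens(key))


def match_pop(
    pop: Union[str, Pair],
    pecs: Iterable[Union[str, Pair]],
    pk_table: Optional[PkClassTable] = None,
) -> MatchResult:
    """Score one POP against a compound's PEC set.

    Polyketide-class pooling is applied to both sides before comparison;
    the three-way exact / partial / none partition is described in the
    module docstring.  ``matched_pec`` reports the first PEC (sorted by
    key) whose pooled form equals the pooled POP.
    """
    table = pk_table or PkClassTable.default()
    key = _key_of(pop)
    pec_keys = sorted(_key_of(p) for p in pecs)
    mapped = _map_key(key, table)
    for pec in pec_keys:
        if _map_key(pec, table) == mapped:
            return MatchResult(pop=key, points=1.0, match_kind=MATCH_EXACT, matched_pec=pec)
    tokens = [pk_classify(t, table) for t in pair_tokens(key)]
    n_nrp = sum(t == NRP_TOKEN for t in tokens)
    if n_nrp == 1:
        others = [t for t in tokens if t != NRP_TOKEN]
        pec_tokens = {
            pk_classify(t, table) for pec in pec_keys for t in pair_tokens(pec)
        }
        if all(t in pec_tokens for t in others):
            return MatchResult(pop=key, points=0.5, match_kind=MATCH_PARTIAL)
    return MatchResult(pop=key, points=0.0, match_kind=MATCH_NONE)


def score_pops(
    pops: PairMultiset,
    compound: CompoundEntry,
    cluster_key: str = "",
    pk_table: Optional[PkClassTable] = None,
    with_multiplicity: bool = False,
    n_gram_size: int = 2,
) -> ClusterScore:
    """Score an already-derived POP multiset against one compound."""
    pec_support = pecs_for(compound, n_gram_size=n_gram_size).support()
    score = ClusterScore(cluster_key=cluster_key or pops.origin, compound=compound.name)
    if not pops.counts:
        score.no_pops = True
        return score
    for key in sorted(pops.counts):
        result = match_pop(key, pec_support, pk_table)
        repeats = pops.counts[key] if with_multiplicity else 1
        score.results.extend([result] * repeats)
    return score


def score_cluster(
    r: ClusterRecord,
    c: CompoundEntry,
    policy: str = "strict",
    pk_table: Optional[PkClassTable] = None,
    with_multiplicity: bool = False,
    n_gram_size: int = 2,
) -> ClusterScore:
    """Score every distinct POP of a cluster record against a compound.

    Distinct POPs are scored once each by default; ``with_multiplicity``
    repeats each result by its occurrence count for sensitivity analysis.
    """
    pops = pops_for(r, policy=policy, n_gram_size=n_gram_size)
    return score_pops(
        pops,
        c,
        cluster_key=r.cluster_key,
        pk_table=pk_table,
        with_multiplicity=with_multiplicity,
        n_gram_size=n_gram_size,
    )


def identity_vs_correctness(
    scores: Iterable[ClusterScore], records: RecordSet
) -> pd.DataFrame:
    """Pair each cluster's homology percentage with its fraction of correct POPs.

    Returns a table (cluster_key, identity_percent, fraction_correct,
    flagged) whose ``attrs`` carry a Spearman rank-correlation summary:
    ``spearman_rho`` is NaN and ``correlation_defined`` False when fewer
    than two unflagged rows exist or either column has zero variance.
    Rows lacking a known-match identity are flagged and excluded from the
    correlation.
    """
    by_key = records.by_key()
    rows = []
    for s in scores:
        rec = by_key.get(s.cluster_key)
        identity = (
            rec.known_match.identity_percent
            if rec is not None and rec.known_match is not None
            else None
        )
        rows.append(
            {
                "cluster_key": s.cluster_key,
                "identity_percent": np.nan if identity is None else float(identity),
                "fraction_correct": s.fraction_correct,
                "flagged": identity is None or s.no_pops,
            }
        )
    df = pd.DataFrame(rows, columns=["cluster_key", "identity_percent", "fraction_correct", "flagged"])
    usable = df[~df["flagged"]]
    rho, pval, defined = math.nan, math.nan, False
    if len(usable) >= 2:
        x = usable["identity_percent"].to_numpy()
        y = usable["fraction_correct"].to_numpy()
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            rho, pval = stats.spearmanr(x, y)
            defined = True
    df.attrs.update(
        {"spearman_rho": rho, "spearman_p": pval, "correlation_defined": defined}
    )
    return df


def write_score_report(
    scores: Iterable[ClusterScore], records: RecordSet, path
) -> None:
    """Per-POP score report TSV: cluster, compound, pop, points, kind, identity."""
    by_key = records.by_key()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cluster_key\tcompound\tpop\tpoints\tmatch_kind\tidentity_percent\n")
        for s in scores:
            rec = by_key.get(s.cluster_key)
            identity = (
                rec.known_match.identity_percent
                if rec is not None and rec.known_match is not None
                else ""
            )
            for r in s.results:
                fh.write(
                    f"{s.cluster_key}\t{s.compound}\t{r.pop}\t{r.points}\t{r.match_kind}\t{identity}\n"
                )


def write_score_summary(scores: Iterable[ClusterScore], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cluster_key\tcompound\tn_pops\ttotal_points\tfraction_correct\tno_pops\n")
        for s in scores:
            fh.write(
                f"{s.cluster_key}\t{s.compound}\t{s.n_pops}\t{s.total_points}\t"
                f"{s.fraction_correct:.6f}\t{int(s.no_pops)}\n"
            )
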