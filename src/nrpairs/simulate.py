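"""Synthetic gene-cluster cohorts with controlled prediction corruption.

The generator emulates a validation cohort like the Delftibactin one:
clusters homologous to a template compound whose per-module predictions
degrade as genomic identity drops.  Corruption acts *before* consensus,
at the level of the three predictor calls, so the unresolved ``nrp``
token arises mechanistically from predictor discordance rather than
being injected into the backbone:

* with probability ``nrp_rate × g(identity)`` a module's three predictors
  return three different tokens (consensus → ``nrp``);
* with probability ``wrong_monomer_rate × g(identity)`` all three agree
  on the same decoy token (a confidently wrong call);
* otherwise all three agree on the template's true monomer.

``g`` links identity to corruption: linear by default
(``g = 1 − identity/100``, so a 100 %-identity cluster is uncorrupted),
or ``none`` to apply the base rates verbatim at every identity level.
Default condition: 500 clusters spread over identity levels
100/75/50/25 %, spanning roughly the 9–100 % homology range a real
cohort exhibits.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigError
from .ingest import ClusterRecord, KnownMatch, RecordSet
from .library import CompoundEntry, get_compound, load_compound_library
from .monomer import NRP_TOKEN, PREDICTORS, PredictorCalls, normalize_monomer

#: Decoy monomers drawn for wrong/discordant calls; disjoint from the
#: Delftibactin backbone tokens and from ``nrp``.
DEFAULT_DECOYS = ("ala", "val", "leu", "ile", "cys", "glu", "gln", "lys", "pro", "dab")

IDENTITY_LINKS = ("linear", "none")


def default_template() -> CompoundEntry:
    return get_compound(load_compound_library(), "Delftibactin")


@dataclass
class SynthConfig:
    """Parameters of one synthetic cohort."""

    template: Optional[CompoundEntry] = None
    n_clusters: int = 500
    identity_levels: Sequence[float] = (100.0, 75.0, 50.0, 25.0)
    wrong_monomer_rate: float = 0.15
    nrp_rate: float = 0.30
    vocabulary: Sequence[str] = DEFAULT_DECOYS
    identity_link: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template is None:
            self.template = default_template()
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be positive")
        if not self.identity_levels:
            raise ConfigError("identity_levels must be nonempty")
        if any(not 0.0 <= v <= 100.0 for v in self.identity_levels):
            raise ConfigError("identity levels must lie in [0, 100]")
        if not 0.0 <= self.wrong_monomer_rate <= 1.0 or not 0.0 <= self.nrp_rate <= 1.0:
            raise ConfigError("corruption rates must be probabilities")
        if self.wrong_monomer_rate + self.nrp_rate > 1.0:
            raise ConfigError("wrong_monomer_rate + nrp_rate must not exceed 1")
        if NRP_TOKEN in {str(v).lower() for v in self.vocabulary}:
            raise ConfigError("decoy vocabulary must not contain the nrp token")
        if len(self.vocabulary) < 2:
            raise ConfigError("need at least two decoy tokens for discordant calls")
        if self.identity_link not in IDENTITY_LINKS:
            raise ConfigError(f"identity_link must be one of {IDENTITY_LINKS}")


def _corruption_scale(identity: float, link: str) -> float:
    return 1.0 - identity / 100.0 if link == "linear" else 1.0


def _module_calls(
    truth: str,
    p_nrp: float,
    p_wrong: float,
    decoys: Sequence[str],
    rng: np.random.Generator,
) -> PredictorCalls:
    u = rng.random()
    if u < p_nrp:
        # Three mutually distinct tokens: consensus fails under either policy.
        pool = [d for d in decoys if d != truth]
        picks = rng.choice(len(pool), size=2, replace=False)
        tokens = [truth, pool[picks[0]], pool[picks[1]]]
        rng.shuffle(tokens)
    elif u < p_nrp + p_wrong:
        pool = [d for d in decoys if d != truth]
        tokens = [pool[rng.integers(len(pool))]] * 3
    else:
        tokens = [truth] * 3
    return PredictorCalls(calls=dict(zip(PREDICTORS, tokens)))


def simulate_records(cfg: SynthConfig) -> RecordSet:
    """Generate a cohort of clusters derived from the template backbone.

    Identity levels are assigned round-robin across clusters; per-module
    corruption probabilities are the base rates scaled by the cluster's
    identity link.  Equal configs (including seed) give identical record
    sets.
    """
    rng = np.random.default_rng(cfg.seed)
    truth_tokens = [m.token for m in cfg.template.backbone.monomers]
    decoys = [normalize_monomer(v).token for v in cfg.vocabulary]
    records: list[ClusterRecord] = []
    for i in range(cfg.n_clusters):
        identity = float(cfg.identity_levels[i % len(cfg.identity_levels)])
        scale = _corruption_scale(identity, cfg.identity_link)
        p_nrp = cfg.nrp_rate * scale
        p_wrong = cfg.wrong_monomer_rate * scale
        modules = [
            _module_calls(tok, p_nrp, p_wrong, decoys, rng) for tok in truth_tokens
        ]
        records.append(
            ClusterRecord(
                organism=f"SynthOrg_{i + 1:04d}",
                genome_accession=f"SYN{i + 1:07d}",
                cluster_index=1,
                cluster_type="NRPS-T1PKS",
                modules=modules,
                known_match=KnownMatch(
                    compound_name=cfg.template.name,
                    mibig_id=cfg.template.mibig_id,
                    identity_percent=identity,
                ),
            )
        )
    return RecordSet(records=records, provenance=f"simulated seed={cfg.seed}")


def simulate_outlier(cfg: SynthConfig, divergent_fraction: float) -> RecordSet:
    """Cohort with a fraction of high-identity but heavily corrupted clusters.

    The base cohort is generated exactly as :func:`simulate_records`;
    a ``divergent_fraction`` of clusters (chosen with a seed-derived RNG)
    are then relabeled to the maximum identity level while their modules
    are regenerated under heavy corruption (45 % discordant + 45 % wrong
    per module).  ``divergent_fraction = 0`` returns the base cohort
    unchanged.
    """
    if not 0.0 <= divergent_fraction <= 1.0:
        raise ConfigError("divergent_fraction must lie in [0, 1]")
    rs = simulate_records(cfg)
    n_out = int(round(divergent_fraction * len(rs.records)))
    if n_out == 0:
        return rs
    rng = np.random.default_rng(cfg.seed + 1)
    chosen = rng.choice(len(rs.records), size=n_out, replace=False)
    truth_tokens = [m.token for m in cfg.template.backbone.monomers]
    decoys = [normalize_monomer(v).token for v in cfg.vocabulary]
    top = max(float(v) for v in cfg.identity_levels)
    for idx in sorted(int(i) for i in chosen):
        old = rs.records[idx]
        rs.records[idx] = ClusterRecord(
            organism=old.organism,
            genome_accession=old.genome_accession,
            cluster_index=old.cluster_index,
            cluster_type=old.cluster_type,
            modules=[
                _module_calls(tok, 0.45, 0.45, decoys, rng) for tok in truth_tokens
            ],
            known_match=KnownMatch(
                compound_name=old.known_match.compound_name,
                mibig_id=old.known_match.mibig_id,
                identity_percent=top,
            ),
        )
    return rs
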