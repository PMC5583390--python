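"""Shared fixtures: the bundled validation compound and record builders."""

import pytest

from nrpairs import (
    ClusterRecord,
    KnownMatch,
    PredictorCalls,
    RecordSet,
    get_compound,
    load_compound_library,
    pecs_for,
)
from nrpairs.monomer import PREDICTORS


def unanimous(token):
    """A module on which all three predictors agree."""
    return PredictorCalls(calls={name: token for name in PREDICTORS})


def discordant(t1="ser", t2="gly", t3="thr"):
    """A module with three different calls: consensus resolves to nrp."""
    return PredictorCalls(calls=dict(zip(PREDICTORS, (t1, t2, t3))))


def make_record(
    tokens,
    organism="Test organism",
    cluster_index=1,
    identity=None,
    compound="Delftibactin",
    mibig="BGC0000984",
    cluster_type="NRPS",
):
    """Record whose consensus backbone equals ``tokens`` (nrp via 'nrp')."""
    known = None
    if identity is not None:
        known = KnownMatch(compound_name=compound, mibig_id=mibig, identity_percent=identity)
    return ClusterRecord(
        organism=organism,
        cluster_index=cluster_index,
        cluster_type=cluster_type,
        modules=[unanimous(t) for t in tokens],
        known_match=known,
    )


@pytest.fixture(scope="session")
def library():
    return load_compound_library()


@pytest.fixture(scope="session")
def delftibactin(library):
    return get_compound(library, "Delftibactin")


@pytest.fixture(scope="session")
def delftibactin_pecs(delftibactin):
    return pecs_for(delftibactin)


@pytest.fixture()
def record_set():
    """Small mixed record set: scored cluster, draft cluster, unknown match."""
    records = [
        make_record(["orn", "ser"], organism="Org A", cluster_index=1, identity=100.0),
        ClusterRecord(organism="Org B", cluster_index=2, modules=[]),
        make_record(["asp", "ser", "orn"], organism="Org C", cluster_index=1),
    ]
    return RecordSet(records=records)
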