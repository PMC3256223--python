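import pytest

from mirflux.model import (
    Arc,
    ArcRole,
    BioEntity,
    ModelNetwork,
    Reaction,
    ReactionType,
    build_model,
)
from mirflux.synthetic import paper_fixture


@pytest.fixture(scope="session")
def fixture_inputs():
    """The packaged pathway spec and miRNA-target table."""
    return paper_fixture()


@pytest.fixture(scope="session")
def fixture_model(fixture_inputs):
    """The desk-scale EGFR pathway with anti-miRNA inhibitors attached."""
    spec, table = fixture_inputs
    return build_model(spec, table, with_anti_mirnas=True)


@pytest.fixture()
def worked_example():
    """The five-place phosphorylation net printed in the methods example.

    BAD-1 + ATP -> P-BAD-1 + ADP, catalyzed by P-AKT, with the per-step
    transfer fixed at 0.05.
    """
    m = ModelNetwork()
    for eid, role, conc in [
        ("BAD-1", "protein", 1.0),
        ("ATP", "compound", 2.0),
        ("P-AKT", "protein", 3.0),
        ("P-BAD-1", "protein", 0.0),
        ("ADP", "compound", 0.0),
    ]:
        m.add_entity(BioEntity(eid, role, "cytoplasm"))
        m.set_initial(eid, conc)
    rid = "t1"
    m.add_reaction(Reaction(rid, ReactionType.PHOSPHORYLATION, [
        Arc("BAD-1", rid, "input", ArcRole.SUBSTRATE),
        Arc("ATP", rid, "input", ArcRole.SUBSTRATE),
        Arc("P-AKT", rid, "input", ArcRole.ENZYME),
        Arc("P-BAD-1", rid, "output", ArcRole.PRODUCT),
        Arc("ADP", rid, "output", ArcRole.PRODUCT),
    ], k=0.35, flux_override=0.05))
    return m
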