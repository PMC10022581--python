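import numpy as np
import pytest

from ropespace.entity import Entity, admit_member, build_torsion_table
from ropespace.geometry import extract_internal, internal_from_sequence
from ropespace.ideal import IdealGeometry
from ropespace.space import TorsionSpace
from ropespace.synthetic import EnsembleSpec, generate_ensemble


@pytest.fixture(scope="session")
def geometry():
    return IdealGeometry.default()


@pytest.fixture(scope="session")
def helix20():
    """20-residue all-alanine helical chain on ideal geometry."""
    internal = internal_from_sequence("A" * 20, model_name="helix20_A")
    return internal, internal.to_chain()


@pytest.fixture(scope="session")
def mixed_chain():
    """Chain containing every standard residue type."""
    internal = internal_from_sequence("ACDEFGHIKLMNPQRSTVWY",
                                      model_name="mixed_A")
    return internal, internal.to_chain()


def ensemble_space(spec: EnsembleSpec, refine=False):
    """Build the torsion space for a generated ensemble (shared helper)."""
    chains, truth = generate_ensemble(spec)
    entity = Entity("synthetic", spec.sequence)
    for chain in chains:
        admit_member(entity, chain)
    if refine:
        from ropespace.refine import refine_torsions

        refined = {}
        for chain, _ in entity.members:
            internal = extract_internal(chain)
            refined[chain.model_name] = refine_torsions(chain, internal).refined
    else:
        refined = {c.model_name: extract_internal(c) for c, _ in entity.members}
    table = build_torsion_table(entity, refined)
    space = TorsionSpace(table).fit()
    return entity, table, space, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
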