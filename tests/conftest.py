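import pytest
from hypothesis import settings

import pepsig as ps

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from pepsig import synthetic as syn

POOL_SEED = 20260925


@pytest.fixture(scope="session")
def planted_pool():
    """Default study pool: 3 families x 4 subfamilies x 20 proteins, 70 motifs, no mutation."""
    spec = syn.SyntheticSpec(seed=POOL_SEED)
    proteins, truth = syn.generate_family_pool(spec)
    return spec, proteins, truth


@pytest.fixture(scope="session")
def planted_groups(planted_pool):
    """Subfamilies built per family from the planted pool."""
    _, proteins, truth = planted_pool
    groups = []
    for fam in truth.families:
        fam_proteins = [p for p in proteins if truth.protein_truth[p.id][0] == fam]
        built, unassigned = ps.build_subfamilies(fam_proteins, ps.PPRConfig(), family=fam)
        assert not unassigned
        groups.extend(built)
    return groups


@pytest.fixture(scope="session")
def group_to_subfamily(planted_pool, planted_groups):
    """Map each recovered group id to the planted subfamily of its members."""
    _, _, truth = planted_pool
    mapping = {}
    for g in planted_groups:
        subfams = {truth.protein_truth[m][1] for m in g.members}
        assert len(subfams) == 1, f"group {g.id} mixes subfamilies {subfams}"
        mapping[g.id] = subfams.pop()
    return mapping
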