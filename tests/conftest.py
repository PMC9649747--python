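import pytest

from megastitch import TubeParams, make_tube, plan_fragments


@pytest.fixture(scope="session")
def tube900():
    """Standard benchmark tube: 900 residues, 300 Å long, 6 Å lumen."""
    params = TubeParams(n_res=900, length=300.0, inner_wall_radius=7.7, seed=7)
    model, truth = make_tube(params)
    return model, truth


@pytest.fixture(scope="session")
def tube_plan():
    """3-fragment overlapping plan covering the 900-residue tube."""
    return plan_fragments(900, target_len=350, min_overlap=75, max_len=900)


@pytest.fixture()
def small_tube():
    """Small tube for quadratic brute-force oracles."""
    params = TubeParams(n_res=200, length=120.0, inner_wall_radius=7.7, seed=3)
    return make_tube(params)
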