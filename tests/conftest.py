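import numpy as np
import pytest

import stressfiber as sf


@pytest.fixture(scope="session")
def default_params():
    return sf.default_parameters()


@pytest.fixture()
def tiny_params(default_params):
    """A very small fiber for fast structural tests."""
    return default_params.replace(
        n_filaments_per_bundle=3, n_motor=6, n_crosslinker=12,
        g_actin_init=2000, sync_dt=0.5, seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_decorated_bundle(seed=0, n_filaments=4, n_beads=5, jitter=4.0,
                            n_linkers=3, n_motors=2):
    """A static bundle with jittered beads and a few bound springs, for
    gradient and energy-consistency checks."""
    from stressfiber.chemistry import bind_pair
    from stressfiber.synthetic import generate_static_bundle

    rng = np.random.default_rng(seed)
    p = sf.default_parameters().replace(
        n_crosslinker=max(8, n_linkers), n_motor=max(8, n_motors), seed=seed)
    state = generate_static_bundle(spacing=34.0, n_filaments=n_filaments,
                                   n_beads=n_beads, params=p, seed=seed)
    for f in state.filaments.values():
        f.beads = f.beads + jitter * rng.standard_normal(f.beads.shape)
    fids = sorted(state.filaments)
    made = 0
    for i in range(n_linkers):
        fa, fb = fids[i % len(fids)], fids[(i + 1) % len(fids)]
        ba = int(rng.integers(n_beads))
        bb = int(rng.integers(n_beads))
        if ((fa, ba) in state.occupied_linker) or ((fb, bb) in state.occupied_linker):
            continue
        bind_pair(state, "linker", (fa, ba), (fb, bb))
        made += 1
    for i in range(n_motors):
        fa, fb = fids[i % len(fids)], fids[(i + 2) % len(fids)]
        if fa == fb:
            continue
        ba = int(rng.integers(n_beads))
        bb = int(rng.integers(n_beads))
        if ((fa, ba) in state.occupied_motor) or ((fb, bb) in state.occupied_motor):
            continue
        bind_pair(state, "motor", (fa, ba), (fb, bb))
    return state


@pytest.fixture(scope="session")
def steady_run():
    """One default-configuration development run shared by the slow
    acceptance-level tests (coarse sync, ~600 s of simulated time)."""
    from stressfiber.experiments import default_run

    return default_run(seed=11, t_end=600.0, sync_dt=0.5,
                       snapshot_times=(500.0, 550.0))
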