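import math

import numpy as np
import pytest

import poremorph as pm


@pytest.fixture(scope="session")
def monomer():
    return pm.make_monomer_fixture(rng_seed=1)


@pytest.fixture(scope="session")
def partition(monomer):
    from poremorph.metrics import partition_from_fixture
    return partition_from_fixture(monomer)


@pytest.fixture(scope="session")
def ring_topo():
    """Leveled, noiseless, dilation-free render of a default 30-ring."""
    spec = pm.scene_for_particle(pm.ParticleSpec(center=(0.0, 0.0)),
                                 pixel_size=0.5)
    return pm.level_and_zero(pm.render_scene(spec))


def spacing_matched_diameter(n: int) -> float:
    """Crest diameter giving the default per-subunit crest spacing."""
    return n * 26.3 / 30


def render_ring(n: int, *, noise_sd: float = 0.0, tip_radius: float = 0.0,
                rng_seed: int = 0, phase_deg: float = 0.0,
                pore: bool = False):
    """One-particle leveled scene of an n-ring at matched crest spacing."""
    p = pm.ParticleSpec(center=(0.0, 0.0), n_subunits=n,
                        crest_diameter=spacing_matched_diameter(n),
                        phase_deg=phase_deg,
                        lumen_depth=-3.0 if pore else 0.0)
    spec = pm.scene_for_particle(p, pixel_size=0.5, noise_sd=noise_sd,
                                 tip_radius=tip_radius, rng_seed=rng_seed)
    return pm.level_and_zero(pm.render_scene(spec)), spec.particles[0]


def crest_modulation_amplitude(n: int) -> float:
    """Half peak-to-trough of the noiseless crest signal of an n-ring."""
    from poremorph.symmetry import polar_unwrap
    topo, p = render_ring(n)
    c = (topo.extent_nm[1] / 2, topo.extent_nm[0] / 2)
    r = p.crest_diameter / 2
    polar = polar_unwrap(topo, c, (r - 0.5, r + 0.5), 16 * n, 4)
    signal = polar.mean(axis=1)
    return (signal.max() - signal.min()) / 2
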