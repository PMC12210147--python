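import numpy as np
import pytest

import sdikit as sk

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def parcellation100():
    return sk.gen_parcellation(100, seed=1)


@pytest.fixture(scope="session")
def basis60():
    """Harmonic basis of a 60-region synthetic connectome with cutoff 12."""
    p = sk.gen_parcellation(60, seed=2)
    sc = sk.gen_structural_connectome(p, density=0.25, seed=2)
    A, _ = sk.symmetric_normalize(sk.volume_normalize(sc, p.volume))
    return sk.harmonics(A, source="test").with_cutoff(12)


@pytest.fixture(scope="session")
def effect_cohort():
    """Midsize cohort with a planted group effect, reused across tests."""
    p = sk.gen_parcellation(80, seed=3)
    spec = sk.CohortSpec(
        n_regions=80,
        n_timepoints=300,
        n_per_group=(25, 25),
        effect_regions=tuple(range(4, 80, 10)),
        effect_size=2.5,
        severity_link_regions=tuple(range(4, 80, 10)),
        severity_rho=-0.5,
        seed=3,
    )
    return sk.gen_cohort(spec, p)


def ring_adjacency(n):
    """Unit-weight cycle graph; regular, so its first harmonic is constant."""
    sc = np.zeros((n, n))
    for i in range(n):
        sc[i, (i + 1) % n] = sc[(i + 1) % n, i] = 1.0
    return sc
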