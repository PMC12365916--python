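import numpy as np
import pytest

import dohaplo as dh


@pytest.fixture(scope="session")
def small_panel():
    """200 segregating markers on a 10 Mb chromosome."""
    return dh.simulate_founder_panel(200, 10_000_000, seed=11)


@pytest.fixture(scope="session")
def ibd_panel():
    """Panel with two engineered classical-founder IBD blocks."""
    spec = [(("B", "C"), 2_000_000, 4_000_000),
            (("A", "D"), 6_000_000, 7_500_000)]
    return dh.simulate_founder_panel(400, 10_000_000, ibd_spec=spec,
                                     seed=17)


@pytest.fixture(scope="session")
def cohort(small_panel):
    """Three mosaics + 1x depths on the small panel."""
    mos = dh.simulate_do_diplotypes(small_panel, 41, 3, seed=23)
    depths = dh.simulate_read_cohort(mos, small_panel, 1.0, seed=29)
    return mos, depths


def truth_alleleprobs(mosaic, panel):
    """Point-mass allele probabilities from a truth mosaic."""
    fnd = mosaic.founders_at(panel.positions)
    out = np.zeros((panel.n_markers, 8))
    for h in range(2):
        np.add.at(out, (np.arange(panel.n_markers), fnd[:, h]), 0.5)
    return out
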