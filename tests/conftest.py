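"""Shared fixtures: scaled-down dyads so the suite stays fast.

Expensive simulations are session-scoped. The tiny fixtures use a
4-channel montage and short sessions; they exercise the same code paths as
the full 14-channel study layout, which is covered once in the
pipeline-shape tests.
"""

import numpy as np
import pytest

from interbrain.offline import dyad_spectrum, task_related
from interbrain.simulate import DyadSimConfig, simulate_dyad
from interbrain.timeline import make_timeline

FOUR_CH = ("F3", "F4", "P7", "P8")


@pytest.fixture(scope="session")
def tiny_timeline():
    """One 40-s feedback round, two 21-s rest blocks (97 s total)."""
    return make_timeline(n_rounds=1, round_s=40.0, rest_s=21.0)


@pytest.fixture(scope="session")
def small_timeline():
    """One 55-s round, two 30-s rest blocks (135 s total)."""
    return make_timeline(n_rounds=1, round_s=55.0, rest_s=30.0)


def make_dyad(kappa, seed, timeline, channels=FOUR_CH, **overrides):
    cfg = DyadSimConfig(coupling_strength=kappa, seed=seed,
                        channel_labels=tuple(channels), **overrides)
    return simulate_dyad(cfg, timeline)


def task_related_spectrum(rec, discard_tail_s=10.0):
    task = dyad_spectrum(rec, "task", discard_tail_s=discard_tail_s)
    rest = dyad_spectrum(rec, "rest")
    return task_related(task, rest)


@pytest.fixture(scope="session")
def coupled_dyad(small_timeline):
    """14-channel dyad with kappa=0.8 injected at 21-23 Hz."""
    return simulate_dyad(DyadSimConfig(coupling_strength=0.8, seed=7),
                         small_timeline)


@pytest.fixture(scope="session")
def kappa_grid_spectra(tiny_timeline):
    """Task-related band coupling for kappa in {0,.25,.5,.75,1} x 20 seeds.

    Returns (kappas, spectra) with spectra shaped (n_kappa, n_seeds, 30);
    computed once and reused by the monotonicity and band-specificity
    property tests.
    """
    kappas = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    n_seeds = 20
    out = np.empty((len(kappas), n_seeds, 30))
    for i, k in enumerate(kappas):
        for s in range(n_seeds):
            rec = make_dyad(k, 1000 + 61 * s + i, tiny_timeline)
            out[i, s] = task_related_spectrum(rec).values
    return kappas, out
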