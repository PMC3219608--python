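import numpy as np
import pandas as pd
import pytest

from esgamap import benchmarks, plates, scoring, synthgen


@pytest.fixture(scope="session")
def small_truth():
    """Module-structured network with planted effects in both conditions."""
    return synthgen.generate_ground_truth(
        n_genes=40, n_modules=4, within_rate=0.15, between_rate=0.02,
        lethal_fraction=0.10, seed=11)


@pytest.fixture(scope="session")
def small_screens(small_truth):
    noise = synthgen.NoiseModel(multiplicative_cv=0.10, dropout_rate=0.05, seed=12)
    return synthgen.simulate_screens(small_truth, noise=noise)


@pytest.fixture(scope="session")
def scored_rich(small_truth, small_screens):
    """(screen, fitness, EScoreMatrix-with-p) for the rich condition."""
    return benchmarks._score_condition(
        small_screens["rich"], "rich", small_truth.position_bp,
        attach_p=True, seed=13)


def make_screen_matrix(w, sd=None, n_obs=None, queries=None, arrays=None,
                       condition="rich"):
    """Assemble a ScreenMatrix directly from arrays (test helper)."""
    w = np.asarray(w, dtype=float)
    nq, na = w.shape
    queries = queries or [f"q{i}" for i in range(nq)]
    arrays = arrays or [f"a{j}" for j in range(na)]
    sd = np.full_like(w, 0.05) if sd is None else np.asarray(sd, dtype=float)
    n_obs = np.full(w.shape, 3, dtype=int) if n_obs is None else np.asarray(n_obs)
    return plates.ScreenMatrix(queries=list(queries), arrays=list(arrays),
                               w=w, sd=sd, n_obs=n_obs,
                               mask=np.zeros(w.shape, bool), condition=condition)


def make_escore_matrix(e, evar=None, condition="rich", null_abs=None):
    e = np.asarray(e, dtype=float)
    nq, na = e.shape
    return scoring.EScoreMatrix(
        queries=[f"q{i}" for i in range(nq)], arrays=[f"a{j}" for j in range(na)],
        e=e, evar=np.full(e.shape, 0.25) if evar is None else np.asarray(evar),
        condition=condition, sigma0=0.1,
        null_abs=None if null_abs is None else np.sort(np.asarray(null_abs, float)))
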