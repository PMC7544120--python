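"""Shared fixtures: small simulated ensembles reused across the suite.

The session-scoped simulations are the expensive part of the suite; every
test that needs an equilibrated ensemble shares them.
"""

from __future__ import annotations

import numpy as np
import pytest

from tadfold import polymer_sim as ps
from tadfold.preprocess import vectorize


@pytest.fixture(scope="session")
def params() -> ps.PolymerModelParams:
    return ps.PolymerModelParams()


@pytest.fixture(scope="session")
def ref_ensemble(params):
    """Reference-polymer ensemble: 2.5e5 production steps, 2500 frames, with KE."""
    frames, kinetic = ps.run_langevin(
        params, 250_000, 100, seed=101, chromatin_like=False, return_kinetic=True
    )
    return frames, kinetic


@pytest.fixture(scope="session")
def chrom_ensemble(params):
    """Chromatin-like (two-domain) ensemble matching ref_ensemble in size."""
    return ps.run_langevin(params, 250_000, 100, seed=102, chromatin_like=True)


def _features(traj, cutoff=3.0):
    return np.stack(
        [vectorize(ps.contacts_from_conformation(f, cutoff).astype(float)) for f in traj]
    )


@pytest.fixture(scope="session")
def ref_features(ref_ensemble):
    return _features(ref_ensemble[0])


@pytest.fixture(scope="session")
def chrom_features(chrom_ensemble):
    return _features(chrom_ensemble)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
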