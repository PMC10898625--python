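"""Shared fixtures: synthetic study data and a smoke-trained model.

The smoke model is trained once per session under the desk-scale study
conditions (3 synthetic sites, 64x64 canvas, 50 training anatomies per site,
10 paired test anatomies, 1500 steps) and shared by every test that needs a
trained model.
"""

from __future__ import annotations

import pytest

import styleharm as sh
from styleharm import synthetic_sites as syn

SMOKE_SEED = 0
SMOKE_STEPS = 1500


@pytest.fixture(scope="session")
def study():
    """The synthetic multi-site study: specs, dataset, training arrays."""
    from styleharm import experiments as ex

    return ex.make_study(SMOKE_SEED)


@pytest.fixture(scope="session")
def smoke_model(study):
    """Model trained under the desk-scale study conditions; shared across
    the session."""
    from styleharm import experiments as ex

    bundle, history = ex.train_study(study, seed=SMOKE_SEED,
                                     total_steps=SMOKE_STEPS)
    return {"bundle": bundle, "history": history}


@pytest.fixture()
def paired_slices(study):
    """Model-space slices of the paired test set, keyed by site."""
    ds = study["dataset"]
    sites = sorted(study["train_arrays"])
    return {s: [syn.to_model_slice(g[s]) for g in ds.paired_test]
            for s in sites}


@pytest.fixture()
def tiny_bundle():
    """An untrained, fast-to-build bundle for contract tests."""
    cfg = sh.ModelConfig(n_sites=3, canvas=32, base_width=4, d_s=4, d_z=6)
    return sh.build_models(cfg, seed=1)
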