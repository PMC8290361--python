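"""Shared fixtures: small synthetic bundles and the default-scale CV runs.

The default-scale planted and null cross-validation results are expensive
(a couple of minutes each), so they are computed once per session and shared
by every test that asserts on them.
"""

import pytest

import deepgp

# a small but non-trivial panel: 5 diseases, planted signal, sharing, rare class
TOY = dict(
    n_genes=100,
    n_true_genes_per_disease=(12, 10, 8, 6, 2),
    seed=11,
)


@pytest.fixture(scope="session")
def toy_cfg():
    return deepgp.SyntheticConfig(**TOY)


@pytest.fixture(scope="session")
def toy_bundle(toy_cfg):
    return deepgp.generate_bundle(toy_cfg)


@pytest.fixture(scope="session")
def toy_dir(toy_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("toy_bundle")
    deepgp.write_bundle(toy_bundle, d)
    return d


@pytest.fixture(scope="session")
def default_run_config():
    return deepgp.RunConfig(seed=7)


@pytest.fixture(scope="session")
def planted_cv(default_run_config):
    """10-fold CV of the full pipeline on the default planted-signal panel."""
    bundle = deepgp.generate_bundle(deepgp.SyntheticConfig(seed=7))
    inputs = deepgp.prepare_inputs(bundle.tables(), default_run_config)
    return deepgp.cross_validate(inputs, default_run_config)


@pytest.fixture(scope="session")
def null_cv(default_run_config):
    """Same protocol on the signal-free null panel."""
    bundle = deepgp.generate_null_bundle(deepgp.SyntheticConfig(seed=7))
    inputs = deepgp.prepare_inputs(bundle.tables(), default_run_config)
    return deepgp.cross_validate(inputs, default_run_config)
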