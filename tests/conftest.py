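import numpy as np
import pytest

import gatedscanner as g


@pytest.fixture(scope="session")
def chi10():
    return g.chi10_substrate()


@pytest.fixture(scope="session")
def acfg():
    return g.AnalysisConfig()


@pytest.fixture(scope="session")
def wt():
    return g.make_default_params("wildtype")


def make_single_pause_params(base, duration_s: float) -> "g.EnzymeParams":
    """Variant that pauses with certainty and for a nearly fixed duration
    (gamma with very large shape), committing on the first Chi."""
    shape = 1_000_000
    return base.with_(
        p_pause=1.0,
        p_commit=1.0,
        pause_shape=shape,
        pause_scale=duration_s / shape,
        k_iso=0.0,
        k_detach=0.0,
    )


@pytest.fixture(scope="session")
def single_chi():
    return g.SubstrateSpec(length_bp=7700.0, chi_positions=(4588.0,))


def simulate_plateau_trace(duration_s, seed, noise_sd_bp=30.0):
    """Trace with exactly one pause of ~fixed duration at 4588 bp."""
    base = g.make_default_params("wildtype")
    params = make_single_pause_params(base, duration_s)
    sub = g.SubstrateSpec(length_bp=7700.0, chi_positions=(4588.0,))
    path = g.simulate_path(params, sub, seed)
    cfg = g.TraceConfig(noise_sd_bp=noise_sd_bp, seed=seed + 7)
    return g.render_trace(path, cfg)
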