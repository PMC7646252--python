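import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import loxstamp as lx

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design():
    """Default 9-segment alternating design with generated sequences."""
    return lx.CassetteDesign.generate()


@pytest.fixture(scope="session")
def design3():
    """3-segment alternating design (small enough for exhaustive checks)."""
    return lx.CassetteDesign.generate(n_segments=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def zero_noise_run(design):
    """Small noise-free experiment plus its calling output, shared across tests."""
    cfg = lx.SimConfig(
        n_founders=8,
        expansion_per_founder=3,
        reads_per_cell_mean=40,
        reads_per_cell_dispersion=None,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        truncation_prob=0.0,
        contamination_rate=0.0,
        uci_library_size=200,
    )
    truth, reads = lx.simulate_experiment(cfg, design, np.random.default_rng(11))
    whitelist = [
        lx.CellBarcodeRef(r.cell_id, r.barcode, r.upstream, r.downstream)
        for r in truth.cell_whitelist().itertuples()
    ]
    uci_whitelist = set(truth.founders["uci"])
    calls = lx.call_timestamps(
        reads, design.reference_sequences(), whitelist, uci_whitelist
    )
    return cfg, truth, reads, whitelist, uci_whitelist, calls
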