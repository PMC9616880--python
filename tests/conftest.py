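import numpy as np
import pytest

import captorkit as ck
from captorkit.align import accumulate_events, classify_library
from captorkit.profiling import profile_rates
from captorkit.simulate import PoreChannel, PoreModel


def random_dna(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def panel():
    return ck.design_panel(ck.DesignConfig())


@pytest.fixture(scope="session")
def manifest(panel):
    return ck.build_staggered_manifest([a.id for a in panel])


@pytest.fixture(scope="session")
def error_model():
    return ck.build_context_error_model(rng_seed=0)


@pytest.fixture(scope="session")
def unit_pores():
    """Eight channels with error multiplier exactly 1."""
    return PoreModel(tuple(PoreChannel(i + 1) for i in range(8)))


@pytest.fixture(scope="session")
def sample_refs():
    return {f"f{i}": random_dna(400, seed=100 + i) for i in range(4)}


@pytest.fixture(scope="session")
def deep_library(panel, manifest, error_model, unit_pores, sample_refs):
    """The 5x10^4-read library with a known error model, fully classified.

    Session-scoped because simulation + classification dominate the suite's
    runtime; several statistical checks share it.
    """
    reads, truth = ck.simulate_library(
        panel, manifest, sample_refs, error_model, unit_pores,
        ck.SimConfig(n_reads=50_000, rng_seed=0))
    classifications = classify_library(reads, panel)
    events = accumulate_events(classifications, panel)
    profiles = {cid: profile_rates(ev) for cid, ev in events.items()}
    return {"reads": reads, "truth": truth,
            "classifications": classifications, "events": events,
            "profiles": profiles}
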