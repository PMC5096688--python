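import numpy as np
import pytest

from propagon import ModelParams, default_panel


@pytest.fixture(scope="session")
def example_params() -> ModelParams:
    """Reference supercritical parameter set used across the suite."""
    return ModelParams(alpha=100.0, beta=2e-4, gamma=1e-3, mu=7e-3, n0=4)


@pytest.fixture(scope="session")
def panel():
    return default_panel(0)


@pytest.fixture(scope="session")
def panel_by_label(panel):
    return {s.label: s for s in panel}


def random_params(rng: np.random.Generator, supercritical: bool | None = None,
                  max_tries: int = 200) -> ModelParams:
    """Draw a random valid parameter set, optionally conditioned on criticality."""
    from propagon import r0_from_params

    for _ in range(max_tries):
        p = ModelParams(
            alpha=float(10 ** rng.uniform(0.5, 3)),
            beta=float(10 ** rng.uniform(-5, -3)),
            gamma=float(10 ** rng.uniform(-5, -2.3)),
            mu=float(10 ** rng.uniform(-2.6, -1.9)),
            n0=int(rng.integers(2, 7)),
        )
        if supercritical is None:
            return p
        if (r0_from_params(p) > 1.05) == supercritical and (
            supercritical or r0_from_params(p) < 0.95
        ):
            return p
    raise RuntimeError("could not draw requested parameter set")
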