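import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import resistkit as rk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth_small() -> pd.DataFrame:
    """200-probe planted truth used across modules."""
    return rk.make_expression_truth(200, seed=1)


@pytest.fixture(scope="session")
def designs() -> tuple[rk.HybridizationDesign, rk.HybridizationDesign]:
    return rk.vk_design_2011(), rk.vk_design_2012()


@pytest.fixture(scope="session")
def merged_contrasts_zero_noise(truth_small, designs) -> pd.DataFrame:
    """Merged 2011+2012 contrast table from a noise-free simulation."""
    d11, d12 = designs
    i11 = rk.simulate_two_color_experiment(d11, truth_small, 0.0, 0.1, 0.0, seed=2)
    i12 = rk.simulate_two_color_experiment(d12, truth_small, 0.0, 0.1, 0.0, seed=3)
    c11 = rk.fit_contrasts(rk.normalize(i11), d11, [("VKR2011", "MAL2011")])
    c12 = rk.fit_contrasts(
        rk.normalize(i12),
        d12,
        [("VKR2012", "MAL2012"), ("VKR2012", "NG2012"), ("VKR2012", "TEN2012")],
    )
    return pd.concat([c11, c12], ignore_index=True)
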