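import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bh3coop import Condition, LatentParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def latent() -> LatentParams:
    """Default latent model without replicate jitter (deterministic p)."""
    return LatentParams(replicate_log_theta_sd=0.0)


@pytest.fixture
def latent_jitter() -> LatentParams:
    """Default latent model including inter-replicate variability."""
    return LatentParams()


def mc_release_probability(
    condition: Condition,
    latent: LatentParams,
    agent_map,
    n_draws: int = 1_000_000,
    seed: int = 12345,
) -> float:
    """Brute-force Monte-Carlo oracle for the latent release probability.

    Independent of the quadrature path: draws the two guardian buffers,
    applies drug factors and peptide efficiencies, thresholds the sum, and
    composes intrinsic lethality by independent coin flips.
    """
    from bh3coop.simulate import condition_buffer_factors

    rng = np.random.default_rng(seed)
    r_b = rng.lognormal(latent.buffer_log_mean_B, latent.buffer_log_sd_B, n_draws)
    r_m = rng.lognormal(latent.buffer_log_mean_M, latent.buffer_log_sd_M, n_draws)
    f_b, f_m = condition_buffer_factors(condition, agent_map, latent)
    e_b, e_m = latent.peptide_efficiency[condition.peptide]
    released = f_b * (1 - e_b) * r_b + f_m * (1 - e_m) * r_m < latent.momp_threshold
    for exposure in condition.agents:
        spec = agent_map[exposure.agent]
        if exposure.washed_out and spec.reversible_on_washout:
            continue
        if spec.intrinsic_lethality > 0:
            released |= rng.random(n_draws) < spec.intrinsic_lethality
    return float(released.mean())
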