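"""Generative model: buffer kinetics, latent release probability, event draws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from bh3coop import (
    AgentExposure,
    AgentSpec,
    Condition,
    LatentParams,
    Scenario,
    buffer_level,
    latent_release_probability,
    simulate_condition,
    simulate_panel,
)
from bh3coop.errors import ConfigurationError, InvalidParameterError
from conftest import mc_release_probability


class TestBufferLevel:
    @pytest.mark.parametrize(
        ("mechanism", "effect", "t", "half_life", "washed", "expected"),
        [
            ("mcl1_depleter", 1.0, 0.0, 1.0, False, 1.0),
            ("mcl1_depleter", 1.0, 1.0, 1.0, False, 0.5),
            ("mcl1_depleter", 1.0, 4.0, 1.0, False, 0.0625),
            ("bcl2_transcriptional", 1.0, 4.0, 14.0, False, 2 ** (-4 / 14)),
            ("mcl1_reversible_binder", 1.0, 4.0, None, True, 1.0),
            ("bcl2_binder", 0.9, 4.0, None, False, 0.1),
            ("inert", 0.0, 4.0, None, False, 1.0),
        ],
    )
    def test_closed_form(self, mechanism, effect, t, half_life, washed, expected):
        level = buffer_level(mechanism, effect, t, half_life, washed_out=washed)
        assert level == pytest.approx(expected, abs=1e-12)

    def test_irreversible_washout_freezes_at_exposure_end_level(self):
        during = buffer_level("mcl1_depleter", 0.8, 2.0, 1.0)
        after_wash = buffer_level("mcl1_depleter", 0.8, 2.0, 1.0, washed_out=True)
        assert after_wash == during

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            buffer_level("mcl1_depleter", 1.0, -1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            buffer_level("mcl1_depleter", 1.0, 1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            buffer_level("mcl1_depleter", 1.5, 1.0, 1.0)
        with pytest.raises(ConfigurationError):
            buffer_level("unknown", 0.5, 1.0, 1.0)

    @given(
        effect=st.floats(0.0, 1.0),
        t=st.floats(0.0, 48.0),
        dt=st.floats(0.0, 48.0),
        half_life=st.floats(0.1, 20.0),
    )
    def test_monotone_non_increasing_in_time(self, effect, t, dt, half_life):
        first = buffer_level("mcl1_depleter", effect, t, half_life)
        later = buffer_level("mcl1_depleter", effect, t + dt, half_life)
        assert later <= first + 1e-12
        assert 1.0 - effect - 1e-12 <= later <= 1.0 + 1e-12

    @given(t=st.floats(0.0, 40.0), half_life=st.floats(0.1, 20.0))
    def test_full_block_halves_per_half_life(self, t, half_life):
        now = buffer_level("mcl1_depleter", 1.0, t, half_life)
        next_half_life = buffer_level("mcl1_depleter", 1.0, t + half_life, half_life)
        assert next_half_life == pytest.approx(now / 2.0, rel=1e-9)


class TestLatentReleaseProbability:
    def test_control_peptide_baseline_is_low(self, latent):
        p = latent_release_probability(Condition("c", (), "PUMA2A"), latent)
        assert p < 0.05

    def test_full_efficiency_puma_releases_everything(self, latent):
        from dataclasses import replace

        lat = replace(
            latent,
            peptide_efficiency={**latent.peptide_efficiency, "PUMA": (1.0, 1.0)},
        )
        assert latent_release_probability(Condition("c", (), "PUMA"), lat) == 1.0

    def test_single_surviving_buffer_matches_normal_cdf_and_oracle(self, latent):
        """Full MCL-1 synthesis block for 4 h (one-hour half-life) plus a fully
        efficient BAD-BH3 challenge leaves only the 0.0625-scaled MCL-1 buffer:
        closed form Phi((ln theta - ln 0.0625 - mu_M) / sd_M)."""
        from dataclasses import replace

        lat = replace(
            latent, peptide_efficiency={**latent.peptide_efficiency, "BAD": (1.0, 0.0)}
        )
        agent = AgentSpec("depleter", "mcl1_depleter", effect=1.0)
        cond = Condition("c", (AgentExposure("depleter", 0, 4),), "BAD")
        p = latent_release_probability(cond, lat, {"depleter": agent})
        closed_form = norm.cdf(
            (np.log(lat.momp_threshold) - np.log(0.0625) - lat.buffer_log_mean_M)
            / lat.buffer_log_sd_M
        )
        assert p == pytest.approx(closed_form, abs=1e-6)
        oracle = mc_release_probability(cond, lat, {"depleter": agent})
        assert p == pytest.approx(oracle, abs=0.005)

    @pytest.mark.parametrize("peptide", ["NONE", "BAD", "MS1", "PUMA"])
    def test_two_buffer_quadrature_matches_monte_carlo(self, latent, peptide):
        agent = AgentSpec("abt", "bcl2_binder", effect=0.8)
        cond = Condition("c", (AgentExposure("abt", 0, 4),), peptide)
        p = latent_release_probability(cond, latent, {"abt": agent})
        oracle = mc_release_probability(cond, latent, {"abt": agent})
        assert p == pytest.approx(oracle, abs=0.005)

    def test_adding_an_agent_never_decreases_release(self, latent):
        agent = AgentSpec("dep", "mcl1_depleter", effect=0.7)
        for peptide in ("NONE", "BAD", "MS1"):
            p_without = latent_release_probability(Condition("a", (), peptide), latent)
            p_with = latent_release_probability(
                Condition("b", (AgentExposure("dep", 0, 4),), peptide),
                latent,
                {"dep": agent},
            )
            assert p_with >= p_without - 1e-9

    def test_higher_peptide_efficiency_never_decreases_release(self, latent):
        from dataclasses import replace

        previous = 0.0
        for e in (0.0, 0.3, 0.6, 0.9, 0.98):
            lat = replace(
                latent, peptide_efficiency={**latent.peptide_efficiency, "BAD": (e, 0.0)}
            )
            p = latent_release_probability(Condition("c", (), "BAD"), lat)
            assert p >= previous - 1e-9
            previous = p

    def test_washed_reversible_binder_equals_no_drug(self, latent):
        binder = AgentSpec(
            "a477", "mcl1_reversible_binder", effect=0.96, reversible_on_washout=True
        )
        washed = Condition(
            "washed", (AgentExposure("a477", 0, 4, washed_out=True),), "BAD"
        )
        untreated = Condition("untreated", (), "BAD")
        p_washed = latent_release_probability(washed, latent, {"a477": binder})
        p_untreated = latent_release_probability(untreated, latent)
        assert p_washed == pytest.approx(p_untreated, abs=1e-9)

    def test_washout_does_not_rescue_irreversible_depletion(self, latent):
        depleter = AgentSpec("dep", "mcl1_depleter", effect=1.0)
        kept = Condition("kept", (AgentExposure("dep", 0, 4),), "BAD")
        washed = Condition(
            "washed", (AgentExposure("dep", 0, 4, washed_out=True),), "BAD"
        )
        p_kept = latent_release_probability(kept, latent, {"dep": depleter})
        p_washed = latent_release_probability(washed, latent, {"dep": depleter})
        assert p_washed == pytest.approx(p_kept, abs=1e-9)

    def test_unresolvable_agent_reference(self, latent):
        cond = Condition("c", (AgentExposure("ghost", 0, 4),), "NONE")
        with pytest.raises(ConfigurationError):
            latent_release_probability(cond, latent)


def _half_release_latent(latent):
    """BAD-BH3 tuned so the surviving MCL-1 term sits exactly at the median."""
    from dataclasses import replace

    return replace(
        latent, peptide_efficiency={**latent.peptide_efficiency, "BAD": (1.0, 0.3)}
    )


class TestSimulateCondition:
    def test_zero_events_yields_empty_table(self, latent):
        table = simulate_condition(Condition("c", (), "NONE", n_events=0), latent, 1)
        assert table.n_events == 0

    def test_certain_release_marks_every_event(self, latent):
        from dataclasses import replace

        lat = replace(
            latent, peptide_efficiency={**latent.peptide_efficiency, "PUMA": (1.0, 1.0)}
        )
        table = simulate_condition(
            Condition("c", (), "PUMA", n_events=500), lat, seed=7
        )
        assert table.latent_p == 1.0
        assert table.data["latent_released"].all()

    def test_observed_fraction_near_half_probability(self, latent):
        lat = _half_release_latent(latent)
        cond = Condition("c", (), "BAD", n_events=10_000)
        table = simulate_condition(cond, lat, seed=3)
        assert table.latent_p == pytest.approx(0.5, abs=1e-9)
        assert abs(table.data["latent_released"].mean() - 0.5) < 0.015

    def test_same_seed_reproduces_identical_events(self, latent):
        cond = Condition("c", (), "BAD", n_events=1_000)
        t1 = simulate_condition(cond, latent, seed=11)
        t2 = simulate_condition(cond, latent, seed=11)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_fraction_converges_at_binomial_rate(self, latent):
        """Observed released fractions stay within 4 binomial SE of the latent
        probability across 50 seeds at n = 10,000."""
        lat = _half_release_latent(latent)
        cond = Condition("c", (), "BAD", n_events=10_000)
        bound = 4 * np.sqrt(0.5 * 0.5 / 10_000)
        for seed in range(50):
            table = simulate_condition(cond, lat, seed=seed)
            assert abs(table.data["latent_released"].mean() - table.latent_p) < bound

    def test_momp_positive_cells_are_dpsi_low_and_lag_into_aad(self, latent):
        lat = _half_release_latent(latent)
        cond = Condition("c", (), "BAD", n_events=20_000)
        table = simulate_condition(cond, lat, seed=5)
        released = table.data["latent_released"].astype(bool)
        dpsi_low = np.log10(table.data["dpsi_intensity"]) < 2.25
        aad_pos = np.log10(table.data["aad_intensity"]) > 1.75
        # channel separation is 6 sigma: classification error is negligible
        assert (dpsi_low == released).mean() > 0.995
        assert aad_pos[~released].mean() < 0.005  # only the gate's tail leaks
        lag = aad_pos[released].mean()
        assert lag == pytest.approx(lat.aad_lag_prob, abs=0.02)


class TestSimulatePanel:
    def _scenario(self, latent, n_events=400, base_seed=0):
        agent = AgentSpec("dep", "mcl1_depleter", effect=1.0)
        conds = (
            Condition("dep|BAD", (AgentExposure("dep", 0, 4),), "BAD", n_events=n_events),
            Condition("untreated|BAD", (), "BAD", n_events=n_events),
        )
        return Scenario(
            agents=(agent,), conditions=conds, latent=latent, base_seed=base_seed
        )

    def test_one_table_per_condition_replicate(self, latent):
        tables = simulate_panel(self._scenario(latent))
        assert len(tables) == 2 * 3

    def test_same_base_seed_is_fully_reproducible(self, latent_jitter):
        t1 = simulate_panel(self._scenario(latent_jitter))
        t2 = simulate_panel(self._scenario(latent_jitter))
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.data, b.data)
            assert a.latent_p == b.latent_p

    def test_replicates_are_distinct_draws(self, latent):
        lat = _half_release_latent(latent)
        any_difference = False
        for base_seed in range(10):
            tables = simulate_panel(self._scenario(lat, n_events=1_000, base_seed=base_seed))
            counts = [t.data["latent_released"].sum() for t in tables if t.condition_id == "untreated|BAD"]
            if len(set(counts)) > 1:
                any_difference = True
        assert any_difference

    def test_duplicate_condition_ids_rejected(self, latent):
        agent = AgentSpec("dep", "mcl1_depleter", effect=1.0)
        with pytest.raises(ConfigurationError):
            Scenario(
                agents=(agent,),
                conditions=(
                    Condition("same", (), "NONE"),
                    Condition("same", (), "BAD"),
                ),
                latent=latent,
            )


class TestLongPrimingKinetics:
    def test_bcl2_downregulator_needs_prolonged_priming(self):
        """With a 14-h BCL-2 half-life a transcriptional downregulator leaves
        >80% of the buffer after 4 h but <10% after 48 h, which is why a 4-h
        assay cannot see its priming while a 48-h assay can."""
        latent = LatentParams()
        at_4h = buffer_level("bcl2_transcriptional", 1.0, 4.0, latent.half_life_bcl2)
        at_48h = buffer_level("bcl2_transcriptional", 1.0, 48.0, latent.half_life_bcl2)
        assert at_4h > 0.80
        assert at_48h < 0.10
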