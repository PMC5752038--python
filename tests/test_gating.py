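"""Release-gate fitting and percentage readouts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bh3coop import (
    Condition,
    fit_release_threshold,
    percent_release,
    quadrant_fractions,
    default_quadrant_thresholds,
    simulate_condition,
)
from bh3coop.errors import (
    ChannelAbsentError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedMeasurementError,
)


def _mixture_events(rng, n, weight_dim, mean_dim, mean_bright, sd):
    """Labelled two-component log10-normal cytochrome-C events."""
    dim = rng.random(n) < weight_dim
    log10 = rng.normal(np.where(dim, mean_dim, mean_bright), sd)
    return pd.DataFrame({"cytc_intensity": 10.0 ** log10, "latent_released": dim.astype(int)})


def _grid_accuracy_oracle(weight_dim, mean_dim, mean_bright, sd):
    """Brute-force grid search for the threshold maximising classification
    accuracy under the generative two-component mixture."""
    from scipy.stats import norm

    grid = np.linspace(mean_dim, mean_bright, 30_001)
    accuracy = weight_dim * norm.cdf((grid - mean_dim) / sd) + (
        1.0 - weight_dim
    ) * norm.sf((grid - mean_bright) / sd)
    best = grid[accuracy == accuracy.max()]
    return 0.5 * (best.min() + best.max())


class TestFitReleaseThreshold:
    def test_equal_components_give_midpoint(self):
        rng = np.random.default_rng(0)
        events = _mixture_events(rng, 20_000, 0.5, 2.0, 3.5, 0.25)
        fit = fit_release_threshold(events)
        assert np.log10(fit.threshold) == pytest.approx(2.75, abs=0.05)
        assert not fit.fallback
        lo, hi = fit.log10_means
        assert lo < np.log10(fit.threshold) < hi

    def test_unequal_weights_shift_threshold_toward_minor_component(self):
        rng = np.random.default_rng(1)
        events = _mixture_events(rng, 20_000, 0.9, 2.0, 3.5, 0.15)
        fit = fit_release_threshold(events)
        oracle = _grid_accuracy_oracle(0.9, 2.0, 3.5, 0.15)
        assert np.log10(fit.threshold) > 2.75
        assert np.log10(fit.threshold) == pytest.approx(oracle, abs=0.05)

    def test_unimodal_input_falls_back_to_midpoint_and_flags(self):
        rng = np.random.default_rng(2)
        log10 = rng.normal(3.5, 0.25, 5_000)
        events = pd.DataFrame({"cytc_intensity": 10.0 ** log10})
        fit = fit_release_threshold(events)
        assert fit.fallback
        lo, hi = fit.log10_means
        assert np.log10(fit.threshold) == pytest.approx(0.5 * (lo + hi), abs=1e-9)

    def test_too_few_events_rejected(self):
        events = pd.DataFrame({"cytc_intensity": np.full(199, 100.0)})
        with pytest.raises(InsufficientDataError):
            fit_release_threshold(events)


class TestPercentRelease:
    def test_extremes(self):
        above = pd.DataFrame({"cytc_intensity": [10.0, 20.0, 30.0]})
        assert percent_release(above, 5.0).fraction_released == 0.0
        assert percent_release(above, 50.0).fraction_released == 1.0

    def test_tie_counts_as_retained(self):
        events = pd.DataFrame({"cytc_intensity": [1.0, 2.0, 2.0, 3.0]})
        assert percent_release(events, 2.0).fraction_released == 0.25

    def test_label_oracle_on_synthetic_events(self, latent):
        cond = Condition("c", (), "BAD", n_events=10_000)
        table = simulate_condition(cond, latent, seed=9)
        fraction = percent_release(table, 10.0 ** 2.75).fraction_released
        assert abs(fraction - table.data["latent_released"].mean()) < 0.01

    def test_invariant_under_event_permutation(self):
        rng = np.random.default_rng(3)
        events = pd.DataFrame({"cytc_intensity": rng.lognormal(5, 1, 1_000)})
        shuffled = events.sample(frac=1.0, random_state=4).reset_index(drop=True)
        thr = float(np.median(events["cytc_intensity"]))
        assert (
            percent_release(events, thr).fraction_released
            == percent_release(shuffled, thr).fraction_released
        )

    @given(st.lists(st.floats(0.1, 1e4), min_size=1, max_size=50),
           st.floats(1.0, 1e4), st.floats(0.0, 1e4))
    def test_raising_threshold_never_lowers_fraction(self, values, thr, bump):
        events = pd.DataFrame({"cytc_intensity": values})
        low = percent_release(events, thr).fraction_released
        high = percent_release(events, thr + bump).fraction_released
        assert high >= low

    def test_empty_table_and_bad_threshold_rejected(self):
        with pytest.raises(UndefinedMeasurementError):
            percent_release(pd.DataFrame({"cytc_intensity": []}), 10.0)
        with pytest.raises(InvalidParameterError):
            percent_release(pd.DataFrame({"cytc_intensity": [1.0]}), 0.0)

    def test_count_is_integral(self):
        rng = np.random.default_rng(5)
        events = pd.DataFrame({"cytc_intensity": rng.lognormal(5, 1, 777)})
        m = percent_release(events, float(np.median(events["cytc_intensity"])))
        assert abs(m.fraction_released * m.n_events - round(m.fraction_released * m.n_events)) < 0.5


class TestQuadrants:
    def test_all_viable(self):
        events = pd.DataFrame(
            {"dpsi_intensity": [1000.0] * 4, "aad_intensity": [10.0] * 4}
        )
        q = quadrant_fractions(events, 100.0, 50.0)
        assert (q.viable, q.dpsi_low_only, q.dpsi_low_aad_pos, q.aad_pos_only) == (
            1.0, 0.0, 0.0, 0.0,
        )

    def test_fractions_partition_to_one(self, latent):
        cond = Condition("c", (), "BAD", n_events=5_000)
        table = simulate_condition(cond, latent, seed=21)
        q = quadrant_fractions(table, 10.0 ** 2.25, 10.0 ** 1.75)
        assert sum(q.as_dict().values()) == pytest.approx(1.0, abs=1e-9)

    def test_generative_momp_and_lag_fractions(self, latent):
        """With MOMP fraction p and dye-lag probability q the quadrant split is
        dpsi-low-only ~ p(1-q) and double-positive ~ pq."""
        from conftest import mc_release_probability

        cond = Condition("c", (), "BAD", n_events=20_000)
        table = simulate_condition(cond, latent, seed=22)
        p = table.latent_p
        q_lag = latent.aad_lag_prob
        q = quadrant_fractions(table, 10.0 ** 2.25, 10.0 ** 1.75)
        se = np.sqrt(p * (1 - p) / table.n_events)
        assert q.dpsi_low_only == pytest.approx(p * (1 - q_lag), abs=3 * se)
        assert q.dpsi_low_aad_pos == pytest.approx(p * q_lag, abs=3 * se)

    def test_missing_channel_rejected(self):
        events = pd.DataFrame({"dpsi_intensity": [1.0, 2.0]})
        with pytest.raises(ChannelAbsentError):
            quadrant_fractions(events, 1.0, 1.0)

    def test_default_thresholds_sit_in_the_control_tails(self, latent):
        control = simulate_condition(
            Condition("untreated", (), "NONE", n_events=20_000), latent, seed=30
        )
        dpsi_thr, aad_thr = default_quadrant_thresholds(control)
        dpsi = control.data["dpsi_intensity"]
        aad = control.data["aad_intensity"]
        assert (dpsi < dpsi_thr).mean() == pytest.approx(0.005, abs=0.002)
        assert (aad > aad_thr).mean() == pytest.approx(0.005, abs=0.002)
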