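"""State classification, file coherence and the cis/trans statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import rootmosaic as rm
from rootmosaic.analysis import OFF, ON, classify_states, file_coherence


def _means(p_on, seed, n_files=80, cells_per_file=8, **kw):
    e = rm.ExpressionModel(p_on=p_on, n_reporters=1, **kw)
    return rm.simulate_cell_means(e, n_files=n_files, cells_per_file=cells_per_file, seed=seed)


def expected_majority_fraction(length, p):
    """Closed form E[max(k, L-k)] / L for k ~ Binomial(L, p)."""
    k = np.arange(length + 1)
    return float(np.sum(binom.pmf(k, length, p) * np.maximum(k, length - k)) / length)


class TestClassification:
    def test_bimodal_population_called_accurately(self):
        t = _means(0.5, seed=7)
        states, margins, info = classify_states(t["mean_reporter_1"].to_numpy())
        assert info.bimodal
        assert (states == t["state_reporter_1"].to_numpy()).mean() >= 0.95
        assert margins.min() >= 0.0 and margins.max() <= 1.0

    @pytest.mark.parametrize("p_on,state", [(1.0, ON), (0.0, OFF)])
    def test_uniform_population_takes_unimodal_path(self, p_on, state):
        t = _means(p_on, seed=3)
        states, _, info = classify_states(t["mean_reporter_1"].to_numpy())
        assert not info.bimodal
        assert (states == state).all()

    def test_identical_intensities_take_unimodal_path(self):
        states, _, info = classify_states(np.full(30, 40.0))
        assert not info.bimodal
        assert (states == ON).all()  # 40 a.u. above the fallback threshold

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            classify_states(np.linspace(1, 10, 19))

    def test_calls_invariant_under_affine_rescaling(self):
        x = _means(0.5, seed=5)["mean_reporter_1"].to_numpy()
        base, _, _ = classify_states(x)
        scaled, _, _ = classify_states(2.5 * x + 10.0)
        assert (base == scaled).all()


class TestHistogramSummary:
    @pytest.mark.parametrize("p_on", [0.3, 0.5, 0.7])
    def test_mixed_population_flags_bimodal(self, p_on):
        t = _means(p_on, seed=11)
        h = rm.histogram_summary(t["mean_reporter_1"].to_numpy())
        assert h.bimodal
        assert h.counts.sum() == len(t)

    @pytest.mark.parametrize("p_on", [0.0, 1.0])
    def test_single_state_population_flags_unimodal(self, p_on):
        t = _means(p_on, seed=11)
        h = rm.histogram_summary(t["mean_reporter_1"].to_numpy())
        assert not h.bimodal

    def test_on_fraction_decreases_with_cold_duration(self):
        fracs = []
        for weeks in [0, 4, 6, 8, 10]:
            per_seed = []
            for s in range(5):
                e = rm.ExpressionModel.from_cold_weeks(weeks, n_reporters=1)
                t = rm.simulate_cell_means(e, n_files=80, cells_per_file=8, seed=50 * s + 1)
                h = rm.histogram_summary(t["mean_reporter_1"].to_numpy())
                per_seed.append(h.on_fraction)
            fracs.append(np.mean(per_seed))
        assert all(a > b for a, b in zip(fracs, fracs[1:]))


class TestFileCoherence:
    def test_perfect_calls_on_coherent_truth_score_one(self):
        e = rm.ExpressionModel(p_on=0.5, n_reporters=1)
        t = rm.simulate_state_table(e, n_files=50, cells_per_file=10, seed=2)
        coh = file_coherence(t)
        assert coh.score == 1.0
        assert (coh.per_file["n_runs"] == 1).all()

    def test_shuffled_states_match_iid_closed_form(self):
        # destroy file structure; i.i.d. Bernoulli(p) cells per file
        p, L, F = 0.7, 12, 150
        e = rm.ExpressionModel(p_on=p, n_reporters=1)
        t = rm.simulate_state_table(e, n_files=F, cells_per_file=L, seed=4)
        rng = np.random.default_rng(0)
        t["state_reporter_1"] = rng.permutation(t["state_reporter_1"].to_numpy())
        realized_p = (t["state_reporter_1"] == ON).mean()
        coh = file_coherence(t)
        expected = expected_majority_fraction(L, realized_p)
        assert coh.score == pytest.approx(expected, abs=3 * 0.1 / np.sqrt(F))

    def test_injected_call_error_lowers_score_to_one_minus_e(self):
        p, L, F, err = 0.5, 12, 150, 0.05
        e = rm.ExpressionModel(p_on=p, n_reporters=1, switch_noise=err)
        t = rm.simulate_state_table(e, n_files=F, cells_per_file=L, seed=6)
        coh = file_coherence(t)
        expected = expected_majority_fraction(L, 1 - err)
        assert coh.score == pytest.approx(expected, abs=3 * 0.06 / np.sqrt(F))
        assert coh.score == pytest.approx(1 - err, abs=0.03)

    def test_length_one_files_are_excluded_from_score(self):
        t = pd.DataFrame(
            {
                "file_id": [0, 0, 1],
                "pos_in_file": [0, 1, 0],
                "state_reporter_1": [ON, OFF, ON],
            }
        )
        coh = file_coherence(t)
        assert coh.score == 0.5  # only the length-2 file counts

    def test_score_invariant_to_file_relabelling(self):
        e = rm.ExpressionModel(p_on=0.5, n_reporters=1, switch_noise=0.1)
        t = rm.simulate_state_table(e, n_files=40, cells_per_file=8, seed=8)
        relabelled = t.copy()
        relabelled["file_id"] = 1000 - relabelled["file_id"]
        assert file_coherence(t).score == file_coherence(relabelled).score


class TestCisTrans:
    def test_trans_data_with_perfect_calls_accepts_null(self):
        e = rm.ExpressionModel(p_on=0.5, n_reporters=2, memory_mode="trans")
        t = rm.simulate_state_table(e, n_files=100, cells_per_file=8, seed=12)
        res = rm.cis_trans_test(t, seed=1)
        assert res.mixed_fraction == 0.0
        assert res.p_value >= 0.05
        assert res.error_rate == 0.0

    def test_cis_data_rejects_null_and_is_symmetric(self):
        e = rm.ExpressionModel(p_on=0.5, n_reporters=2, memory_mode="cis")
        t = rm.simulate_state_table(e, n_files=100, cells_per_file=8, seed=12)
        res = rm.cis_trans_test(t, seed=1)
        assert res.p_value < 0.05
        assert res.n_onoff + res.n_offon > 0
        assert res.p_symmetry > 0.01  # symmetric by construction
        assert abs(res.mixed_fraction - 0.5) < 0.2

    def test_counts_sum_to_file_count(self):
        e = rm.ExpressionModel(p_on=0.3, n_reporters=2, memory_mode="cis")
        t = rm.simulate_state_table(e, n_files=60, cells_per_file=6, seed=3)
        res = rm.cis_trans_test(t, seed=0)
        assert res.n_onon + res.n_onoff + res.n_offon + res.n_offoff == res.n_files

    def test_single_reporter_input_rejected(self):
        e = rm.ExpressionModel(p_on=0.5, n_reporters=1)
        t = rm.simulate_state_table(e, n_files=30, cells_per_file=6, seed=1)
        with pytest.raises(ValueError):
            rm.cis_trans_test(t)

    def test_too_few_files_rejected(self):
        e = rm.ExpressionModel(p_on=0.5, n_reporters=2)
        t = rm.simulate_state_table(e, n_files=5, cells_per_file=6, seed=1)
        with pytest.raises(ValueError):
            rm.cis_trans_test(t)
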