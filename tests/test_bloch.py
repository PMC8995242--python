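"""Bloch engine: signal timeline, steady state, flip-angle optimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blochkwic import (
    SequenceParams,
    TissueParams,
    optimal_flip_bloch,
    optimal_flip_norelax,
    simulate_timeline,
    steady_state_window,
)


class TestValidation:
    def test_rejects_nonphysical_parameters(self):
        with pytest.raises(ValueError):
            SequenceParams(TR=-1.0)
        with pytest.raises(ValueError):
            SequenceParams(alpha=180.0)
        with pytest.raises(ValueError):
            SequenceParams(t_SL_list=(10.0, 5.0))
        with pytest.raises(ValueError):
            SequenceParams(matrix=17)
        with pytest.raises(ValueError):
            TissueParams(T1=-5.0, T1rho0=40.0)
        with pytest.raises(ValueError):
            TissueParams(T1=1400.0, T1rho0=0.0)

    def test_rejects_nonpositive_effective_t1rho(self, myo_seq):
        # negative amplitude can push the linear dispersion model negative
        tissue = TissueParams(T1=1400.0, T1rho0=10.0, m1rho=20.0)
        with pytest.raises(ValueError):
            simulate_timeline(myo_seq, tissue, f_SL=-1000.0)


class TestTimeline:
    def test_zero_flip_gives_zero_signal(self, myo_tissue):
        seq = SequenceParams(alpha=0.0)
        pred = simulate_timeline(seq, myo_tissue, 1500.0)
        assert np.all(pred.signals == 0.0)

    def test_saturation_recovery_closed_form(self):
        # t_SL = 0 and a 90-degree pulse saturate Mz completely, so the
        # steady-state signal is pure saturation recovery over the full
        # cycle, M0 * (1 - exp(-(t_rec + TR) / T1)); with TR << t_rec this
        # is the textbook saturation-recovery expression
        seq = SequenceParams(
            t_SL_list=(0.0,), NR=1, alpha=90.0, n_dummy=80, t_rec=1200.0, TR=5.0
        )
        tissue = TissueParams(T1=900.0, T1rho0=50.0, M0=2.0)
        pred = simulate_timeline(seq, tissue, 0.0)
        expected = 2.0 * (1.0 - np.exp(-(1200.0 + 5.0) / 900.0))
        np.testing.assert_allclose(pred.signals, expected, rtol=1e-9)
        approx = 2.0 * (1.0 - np.exp(-1200.0 / 900.0))
        np.testing.assert_allclose(pred.signals, approx, rtol=5e-3)

    def test_timeline_layout(self, myo_seq, myo_tissue):
        pred = simulate_timeline(myo_seq, myo_tissue, 1500.0)
        W, NR, n_prep = myo_seq.n_weightings, myo_seq.NR, myo_seq.n_prep
        assert len(pred) == n_prep * W * NR
        # each window holds NR consecutive spokes with readout_pos 1..NR
        for win in (0, 5, n_prep * W - 1):
            rows = pred.window_id == win
            assert rows.sum() == NR
            assert list(pred.readout_pos[rows]) == list(range(1, NR + 1))

    def test_high_flip_readout_train_decreases(self, myo_seq, myo_tissue):
        # at 40 degrees the readout train consumes Mz faster than TR recovery
        pred = simulate_timeline(myo_seq, myo_tissue, 1500.0)
        sig = pred.signals.reshape(-1, myo_seq.NR)
        assert np.all(np.diff(sig, axis=1) < 0)

    def test_magnetization_bounds(self, myo_seq, myo_tissue):
        pred = simulate_timeline(myo_seq, myo_tissue, 1500.0)
        assert np.all(pred.signals >= 0.0)
        assert np.all(pred.signals <= myo_tissue.M0)

    def test_steady_state_geometric_convergence(self, myo_seq, myo_tissue):
        # within one block, window-to-window signal changes decay monotonically
        seq = myo_seq.with_(t_SL_list=(20.0,), n_prep=10, n_dummy=0)
        pred = simulate_timeline(seq, myo_tissue, 1500.0)
        first = pred.signals.reshape(-1, seq.NR)[:, 0]
        deltas = np.abs(np.diff(first))
        assert np.all(np.diff(deltas) <= 1e-15)

    def test_first_readout_decreases_with_tsl(self, myo_seq, myo_tissue):
        s1 = [
            steady_state_window(myo_seq, myo_tissue, 1500.0, w)[0]
            for w in range(myo_seq.n_weightings)
        ]
        assert np.all(np.diff(s1) < 0)

    @settings(deadline=None, max_examples=25)
    @given(
        alpha=st.floats(1.0, 90.0),
        t_sl=st.floats(0.0, 120.0),
        t1=st.floats(200.0, 3000.0),
    )
    def test_signal_bounds_property(self, alpha, t_sl, t1):
        seq = SequenceParams(alpha=alpha, t_SL_list=(t_sl,), n_prep=5)
        tissue = TissueParams(T1=t1, T1rho0=40.0)
        pred = simulate_timeline(seq, tissue, 0.0)
        assert np.all(pred.signals >= 0.0)
        assert np.all(pred.signals <= tissue.M0 + 1e-12)


class TestFlipOptimization:
    @pytest.mark.parametrize(
        "nr,expected",
        [(4, 43.51), (1, 90.00), (2, 60.00)],
        # NR=2 checked analytically: d/da[sin a (1+cos a)] = 0
        # => 2 cos^2 a + cos a - 1 = 0 => cos a = 1/2 => a = 60 deg
    )
    def test_closed_form_optimum(self, nr, expected):
        assert optimal_flip_norelax(nr) == pytest.approx(expected, abs=0.005)

    def test_closed_form_rejects_bad_count(self):
        with pytest.raises(ValueError):
            optimal_flip_norelax(0)

    def test_bloch_optimum_myocardial(self, myo_seq, myo_tissue):
        # TR 5, t_rec 1500, t_SL 4..60, NR 4, T1 1400, T1rho 40
        assert optimal_flip_bloch(myo_seq, myo_tissue, f_SL=0.0) == pytest.approx(
            39.35, abs=0.005
        )

    def test_bloch_optimum_converges_to_norelax(self):
        # complete recovery between preparations (t_rec >> T1), no decay
        # during the train (TR << T1) and no spin-lock losses: the
        # simulated optimum must agree with the closed-form train optimum
        seq = SequenceParams(TR=1e-3, t_rec=1e6, t_SL_list=(0.0, 1.0), NR=4)
        tissue = TissueParams(T1=1000.0, T1rho0=1e9)
        a = optimal_flip_bloch(seq, tissue, f_SL=0.0)
        assert a == pytest.approx(optimal_flip_norelax(seq.NR), abs=0.011)

    def test_single_element_grid(self, myo_seq, myo_tissue):
        assert optimal_flip_bloch(
            myo_seq, myo_tissue, f_SL=0.0, alpha_grid=np.array([37.0])
        ) == pytest.approx(37.0)

    def test_empty_grid_rejected(self, myo_seq, myo_tissue):
        with pytest.raises(ValueError):
            optimal_flip_bloch(myo_seq, myo_tissue, 0.0, alpha_grid=np.array([]))
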