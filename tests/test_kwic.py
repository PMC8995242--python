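"""KWIC filter design, density weights and filtered reconstruction."""

import numpy as np
import pytest

from blochkwic import (
    SequenceParams,
    TissueParams,
    build_pattern,
    density_weights,
    design_kwic,
    fibonacci_at_least,
    reconstruct_series,
)
from blochkwic.kwic import RadialKSpace
from blochkwic.nufft import ndft_adjoint, radial_readout, spoke_coordinates


@pytest.fixture(scope="module")
def std_filters(std_pattern):
    return design_kwic(std_pattern, matrix=128, f_nyq=1.1)


class TestDesign:
    def test_annuli_grow_with_fibonacci_counts(self, std_filters):
        fib = {13, 21, 34, 55, 89, 144, 233, 377}
        for filt in std_filters:
            counts = [a.n_phi for a in filt.annuli]
            assert all(c in fib for c in counts)
            assert counts == sorted(counts)
            assert len(set(counts)) == len(counts)

    def test_outermost_annulus_count(self, std_filters):
        # smallest Fibonacci number above pi * 1.1 * 64 ~ 221.2 is 233
        for filt in std_filters:
            assert filt.annuli[-1].n_phi == 233
            assert filt.annuli[-1].r_max >= 64

    def test_innermost_radius_from_nyquist(self, std_filters):
        for filt in std_filters:
            assert filt.annuli[0].r_max == pytest.approx(13 / (np.pi * 1.1), rel=1e-9)

    def test_center_exclusive_to_first_readouts(self, std_pattern, std_filters):
        pred = std_pattern.prediction
        for filt in std_filters:
            inner = set(filt.annuli[0].spoke_set)
            expected = set(
                np.where(
                    (pred.weighting_id == filt.weighting) & (pred.readout_pos == 1)
                )[0]
            )
            assert inner == expected

    def test_spoke_sets_nest(self, std_filters):
        for filt in std_filters:
            for a, b in zip(filt.annuli, filt.annuli[1:]):
                assert set(a.spoke_set) <= set(b.spoke_set)

    def test_nyquist_satisfied_for_all_admitted_samples(self, std_pattern, std_filters):
        k_radii = radial_readout(128)
        r = np.abs(k_radii)
        for filt in std_filters:
            for ann in filt.annuli:
                admitted_r = r[(r >= ann.r_min) & (r < ann.r_max)]
                if admitted_r.size:
                    assert ann.n_phi > np.pi * admitted_r.max() * 1.1

    def test_serial_mode_filters_are_valid(self, phantom_seq):
        prior = TissueParams(T1=1400.0, T1rho0=49.3, m1rho=7.9)
        pat = build_pattern(phantom_seq, prior, 1500.0, mode="serial")
        filters = design_kwic(pat, matrix=128, f_nyq=1.1)
        pred = pat.prediction
        for filt in filters:
            inner = set(filt.annuli[0].spoke_set)
            expected = set(
                np.where(
                    (pred.weighting_id == filt.weighting) & (pred.readout_pos == 1)
                )[0]
            )
            assert inner == expected
            for a, b in zip(filt.annuli, filt.annuli[1:]):
                assert set(a.spoke_set) <= set(b.spoke_set)

    def test_tiny_matrix_single_annulus(self, tiny_seq, myo_tissue):
        # pi * (matrix/2) * f_nyq below the centre count: centre block alone
        pat = build_pattern(tiny_seq.with_(matrix=6), myo_tissue, 1500.0, "bloch")
        filters = design_kwic(pat, matrix=6, f_nyq=1.1)
        for filt in filters:
            assert len(filt.annuli) == 1

    def test_insufficient_spokes_rejected_with_required_count(self, tiny_pattern):
        # 52 spokes cannot satisfy Nyquist at matrix 24 (needs 55)
        with pytest.raises(ValueError, match="55"):
            design_kwic(tiny_pattern, matrix=24, f_nyq=1.1)

    def test_fibonacci_helper(self):
        assert fibonacci_at_least(222) == 233
        assert fibonacci_at_least(13) == 13


class TestDensityWeights:
    def test_ramp_ratio_within_annulus(self, std_pattern, std_filters):
        k_radii = radial_readout(128)
        w = density_weights(std_filters[0], k_radii, std_pattern.n_spokes)
        filt = std_filters[0]
        outer = filt.annuli[-1]
        spoke = outer.spoke_set[0]
        i1 = np.argmin(np.abs(k_radii - 45.0))
        i2 = np.argmin(np.abs(k_radii - 2 * k_radii[i1]))
        assert w[spoke, i2] / w[spoke, i1] == pytest.approx(
            k_radii[i2] / k_radii[i1]
        )

    def test_per_spoke_weight_scales_inversely_with_count(self, std_pattern, std_filters):
        k_radii = radial_readout(128)
        filt = std_filters[0]
        w = density_weights(filt, k_radii, std_pattern.n_spokes)
        # same radius, annuli with different spoke counts
        a1, a2 = filt.annuli[1], filt.annuli[2]
        r1 = (a1.r_min + a1.r_max) / 2
        r2 = (a2.r_min + a2.r_max) / 2
        i1 = np.argmin(np.abs(k_radii - r1))
        i2 = np.argmin(np.abs(k_radii - r2))
        w1 = w[a1.spoke_set[0], i1] / k_radii[i1]
        w2 = w[a2.spoke_set[0], i2] / k_radii[i2]
        assert w1 / w2 == pytest.approx(a2.n_phi / a1.n_phi)

    def test_dc_sample_has_positive_weight(self, std_pattern, std_filters):
        k_radii = radial_readout(128)
        w = density_weights(std_filters[0], k_radii, std_pattern.n_spokes)
        dc_col = np.where(k_radii == 0)[0][0]
        inner = std_filters[0].annuli[0].spoke_set
        assert np.all(w[inner, dc_col] > 0)
        outside = np.setdiff1d(np.arange(std_pattern.n_spokes), inner)
        assert np.all(w[outside, dc_col] == 0)


def _single_contrast_setup(matrix=64, n_spokes=233):
    seq = SequenceParams(
        t_SL_list=(10.0,), n_prep=n_spokes, NR=1, matrix=matrix, fov=32.0
    )
    tissue = TissueParams(T1=1400.0, T1rho0=40.0)
    pat = build_pattern(seq, tissue, 1500.0, mode="bloch")
    k_radii = radial_readout(matrix)
    yy, xx = np.mgrid[0:matrix, 0:matrix]
    img = ((xx - matrix / 2) ** 2 + (yy - matrix / 2) ** 2 < (matrix / 4) ** 2).astype(
        float
    )
    from blochkwic.nufft import nufft_forward

    kx, ky = spoke_coordinates(pat.plan.angle, k_radii)
    samples = nufft_forward(img, kx, ky)
    return pat, k_radii, samples, kx, ky, img


class TestReconstruction:
    def test_zero_kspace_gives_zero_images(self, tiny_pattern, tiny_seq):
        k_radii = radial_readout(tiny_seq.matrix)
        ks = RadialKSpace(
            samples=np.zeros((tiny_pattern.n_spokes, len(k_radii)), dtype=complex),
            angles=tiny_pattern.plan.angle,
            k_radii=k_radii,
            pattern=tiny_pattern,
            f_SL=1500.0,
        )
        filters = design_kwic(tiny_pattern, matrix=tiny_seq.matrix, f_nyq=1.1)
        series = reconstruct_series(ks, filters, matrix=tiny_seq.matrix)
        assert np.all(series.images == 0)

    def test_single_contrast_matches_direct_oracle(self):
        # one weighting, enough spokes for full sampling: the KWIC path
        # reduces to plain density-compensated gridding, which must match
        # the exact direct-summation adjoint with the same weights
        pat, k_radii, samples, kx, ky, img = _single_contrast_setup()
        filters = design_kwic(pat, matrix=64, f_nyq=1.1)
        assert len(filters) == 1 and len(filters[0].annuli) == 1
        w = density_weights(filters[0], k_radii, pat.n_spokes)
        ks = RadialKSpace(
            samples=samples,
            angles=pat.plan.angle,
            k_radii=k_radii,
            pattern=pat,
            f_SL=1500.0,
        )
        series = reconstruct_series(ks, filters, matrix=64, dcf="ramp")
        oracle = np.abs(ndft_adjoint(samples, kx, ky, 64, weights=w))
        rel = np.linalg.norm(series.images[0] - oracle) / np.linalg.norm(oracle)
        assert rel < 1e-3

    def test_reconstruction_linearity(self, tiny_pattern, tiny_seq):
        rng = np.random.default_rng(4)
        k_radii = radial_readout(tiny_seq.matrix)
        shape = (tiny_pattern.n_spokes, len(k_radii))
        k1 = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        k2 = rng.normal(size=shape) + 1j * rng.normal(size=shape)

        def recon(samples):
            ks = RadialKSpace(
                samples=samples,
                angles=tiny_pattern.plan.angle,
                k_radii=k_radii,
                pattern=tiny_pattern,
                f_SL=1500.0,
            )
            filters = design_kwic(tiny_pattern, matrix=tiny_seq.matrix, f_nyq=1.1)
            return reconstruct_series(
                ks, filters, matrix=tiny_seq.matrix, return_complex=True
            ).images

        combo = recon(3.0 * k1 + 2.0 * k2)
        parts = 3.0 * recon(k1) + 2.0 * recon(k2)
        np.testing.assert_allclose(combo, parts, atol=1e-8 * np.abs(parts).max())
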