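"""Line-scan extraction, alignment, colocalization and AUC quantification."""

import numpy as np
import pytest
from scipy import special, stats

from brushborder import profiles as pr
from brushborder import synthetic as syn
from brushborder.errors import (
    CannotAlignError,
    DegenerateLineError,
    InsufficientDataError,
)


def make_pair(ref, marker, spacing=0.01):
    pos = np.arange(len(ref)) * spacing
    prof = pr.LineScanProfile(pos, np.asarray(ref, float), np.asarray(marker, float))
    return pr.normalize_align(prof)


def spearman_first_principles(x, y):
    """Rank correlation from the definition: Pearson on average ranks."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        r[order] = np.arange(1, len(v) + 1)
        for val in np.unique(v):
            mask = v == val
            r[mask] = r[mask].mean()
        return r

    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


# ---------------------------------------------------------------------------
# extraction


class TestExtract:
    def test_constant_image(self):
        img = syn.ImageGrid(np.full((2, 50, 50), 7.0), 0.1)
        prof = pr.extract_line_profile(img, [(0.5, 2.5), (4.5, 2.5)])
        assert np.allclose(prof.ref_intensity, 7.0)
        assert np.allclose(prof.marker_intensity, 7.0)

    def test_width_one_axis_aligned_matches_pixels(self):
        rng = np.random.default_rng(0)
        pix = rng.uniform(0, 10, size=(2, 20, 20))
        img = syn.ImageGrid(pix, 1.0)
        # along row 5 (y = 5.5 um), x from pixel center 2 to pixel center 12
        prof = pr.extract_line_profile(img, [(2.5, 5.5), (12.5, 5.5)], width_px=1)
        np.testing.assert_allclose(prof.ref_intensity, pix[0, 5, 2:13], rtol=1e-9)

    def test_recovers_rendered_marker_peak(self):
        p = syn.gen_line_profiles(
            micro_length=1.0, marker_mode="tip", noise_sd=0.0,
            n_profiles=1, seed=0, length_cv=0.0, center_jitter_sd=0.0,
        )[0]
        # extrude the profile along y into a 2-channel image, scan along x
        img = syn.ImageGrid(
            np.stack([
                np.tile(p.ref_intensity, (24, 1)),
                np.tile(p.marker_intensity, (24, 1)),
            ]),
            pixel_size=p.spacing,
        )
        y_mid = 12 * p.spacing
        prof = pr.extract_line_profile(img, [(0.5 * p.spacing, y_mid),
                                             (400.5 * p.spacing, y_mid)])
        true_peak = p.positions[np.argmax(p.marker_intensity)]
        got_peak = prof.positions[np.argmax(prof.marker_intensity)] + 0.5 * p.spacing
        assert abs(got_peak - true_peak) <= 2 * p.spacing

    def test_degenerate_endpoints_raise(self):
        img = syn.ImageGrid(np.zeros((2, 20, 20)), 1.0)
        with pytest.raises(DegenerateLineError):
            pr.extract_line_profile(img, [(5.0, 5.0), (5.5, 5.0)])


# ---------------------------------------------------------------------------
# normalization / alignment


class TestNormalizeAlign:
    def test_identical_channels_align_at_shared_max(self):
        vals = np.array([1.0, 3.0, 9.0, 3.0, 1.0])
        pair = make_pair(vals, vals)
        np.testing.assert_allclose(pair.ref_norm, pair.marker_norm)
        assert pair.ref_norm[pair.offsets == 0][0] == 1.0

    def test_offset_mapping(self):
        pos = np.arange(0.0, 4.001, 0.5)
        ref = np.zeros(pos.size)
        ref[4] = 200.0  # max at 2.0 um
        prof = pr.LineScanProfile(pos, ref + 1.0, np.ones(pos.size))
        pair = pr.normalize_align(prof)
        assert pair.offsets[2] == pytest.approx(-1.0)  # 1.0 um -> offset -1.0
        assert pair.ref_norm.max() == 1.0

    def test_idempotent(self):
        p = syn.gen_line_profiles(n_profiles=1, seed=3)[0]
        once = pr.normalize_align(p)
        again = pr.normalize_align(
            pr.LineScanProfile(once.offsets - once.offsets[0], once.ref_norm, once.marker_norm)
        )
        np.testing.assert_allclose(once.ref_norm, again.ref_norm)
        np.testing.assert_allclose(once.marker_norm, again.marker_norm)
        np.testing.assert_allclose(once.offsets, again.offsets)

    def test_zero_reference_raises(self):
        prof = pr.LineScanProfile(np.arange(5.0), np.zeros(5), np.ones(5))
        with pytest.raises(CannotAlignError):
            pr.normalize_align(prof)

    def test_envelope_matches_per_offset_recomputation(self):
        profs = syn.gen_line_profiles(n_profiles=10, seed=4, center_jitter_sd=0.0)
        pairs = [pr.normalize_align(p) for p in profs]
        env = pr.profile_envelope(pairs, channel="marker")
        spacing = profs[0].spacing
        # brute force: pool values by rounded offset bin
        pool = {}
        for p in pairs:
            for off, val in zip(p.offsets, p.marker_norm):
                pool.setdefault(round(off / spacing), []).append(val)
        for row in env.itertuples():
            vals = pool[round(row.offset / spacing)]
            assert row.mean == pytest.approx(np.mean(vals))
            assert row.min == pytest.approx(np.min(vals))
            assert row.max == pytest.approx(np.max(vals))


# ---------------------------------------------------------------------------
# colocalization


class TestColoc:
    def test_identical_channels_give_one(self):
        p = syn.gen_line_profiles(n_profiles=1, seed=0, noise_sd=0.03)[0]
        pair = pr.AlignedProfilePair(p.positions, *(2 * [p.ref_intensity / p.ref_intensity.max()]))
        for method in ("spearman", "pearson"):
            res = pr.coloc_coefficient(pair, method=method)
            assert res.coefficient == pytest.approx(1.0)

    def test_antimonotone_marker_gives_minus_one(self):
        rng = np.random.default_rng(2)
        ref = np.sort(rng.uniform(0, 1, 50))
        ref[-1] = 1.0
        pair = pr.AlignedProfilePair(np.arange(50.0), ref, 1.0 - ref)
        res = pr.coloc_coefficient(pair, method="spearman")
        assert res.coefficient == pytest.approx(-1.0)

    def test_missing_when_too_few_samples(self):
        pair = pr.AlignedProfilePair(
            np.arange(5.0), np.array([0.1, 0.2, 1.0, 0.2, 0.1]), np.linspace(0, 1, 5)
        )
        res = pr.coloc_coefficient(pair, threshold=0.7)
        assert res.is_missing and res.n_used == 1 and res.reason

    def test_missing_when_retained_vector_constant(self):
        pair = pr.AlignedProfilePair(
            np.arange(4.0), np.array([0.9, 0.95, 1.0, 0.9]), np.full(4, 0.5)
        )
        assert pr.coloc_coefficient(pair).is_missing

    def test_spearman_matches_first_principles(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = int(rng.integers(10, 60))
            ref = rng.uniform(0.71, 1.0, n)
            ref[rng.integers(n)] = 1.0
            mar = np.clip(ref + rng.normal(0, 0.2, n), 0, 1)
            pair = pr.AlignedProfilePair(np.arange(float(n)), ref, mar)
            res = pr.coloc_coefficient(pair, method="spearman")
            assert res.coefficient == pytest.approx(spearman_first_principles(ref, mar))

    @pytest.mark.parametrize("transform", [np.cbrt, np.exp, lambda v: v**3])
    def test_spearman_invariant_under_monotone_transform(self, transform):
        p = syn.gen_line_profiles(n_profiles=1, seed=6)[0]
        pair = pr.normalize_align(p)
        base = pr.coloc_coefficient(pair)
        twisted = pr.AlignedProfilePair(pair.offsets, pair.ref_norm, transform(pair.marker_norm))
        res = pr.coloc_coefficient(twisted)
        assert res.coefficient == pytest.approx(base.coefficient, abs=1e-12)

    def test_tip_mode_exceeds_delocalized(self):
        def med(mode, seed):
            coefs = []
            for p in syn.gen_line_profiles(micro_length=1.2, marker_mode=mode,
                                           n_profiles=50, seed=seed):
                r = pr.coloc_coefficient(pr.normalize_align(p))
                if not r.is_missing:
                    coefs.append(r.coefficient)
            return np.median(coefs)

        assert med("tip", 1) > med("delocalized", 2)


class TestCompareGroups:
    def test_identical_multisets_p_one(self):
        res = pr.compare_groups([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        res = pr.compare_groups([0.9, 0.91, 0.92], [0.1, 0.11, 0.12])
        assert res.method == "exact"
        assert res.u_statistic == 9
        # oracle: enumerate all C(6,3)=20 labelings of the pooled sample
        from itertools import combinations

        pooled = [0.9, 0.91, 0.92, 0.1, 0.11, 0.12]
        observed_u = 9
        count_extreme = 0
        for idx in combinations(range(6), 3):
            a = [pooled[i] for i in idx]
            b = [pooled[i] for i in range(6) if i not in idx]
            u = sum(1 for x in a for y in b if x > y)
            if min(u, 9 - u) <= min(observed_u, 9 - observed_u):
                count_extreme += 1
        assert res.p_value == pytest.approx(count_extreme / 20) == pytest.approx(0.1)

    def test_nan_coefficients_dropped(self):
        res = pr.compare_groups([0.9, 0.91, 0.92, np.nan], [0.1, 0.11, 0.12])
        assert res.n_a == 3

    def test_insufficient_group_raises(self):
        with pytest.raises(InsufficientDataError):
            pr.compare_groups([0.1, 0.2], [0.3, 0.4, 0.5])

    def test_shift_alternative_detected(self):
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(50):
            a = rng.normal(0.6, 0.15, 30)
            b = a - 0.5
            if pr.compare_groups(a, b).p_value < 0.05:
                rejections += 1
        assert rejections >= 45


# ---------------------------------------------------------------------------
# AUC / lengths


class TestAuc:
    def test_rectangular_pulse(self):
        pos = np.arange(0.0, 4.001, 0.01)
        vals = ((pos >= 1.0) & (pos <= 2.5)).astype(float)
        assert pr.profile_auc(pos, vals) == pytest.approx(1.5, abs=0.011)

    def test_triangle(self):
        pos = np.arange(0.0, 4.001, 0.01)
        vals = np.clip(1.0 - np.abs(pos - 2.0), 0, None)
        assert pr.profile_auc(pos, vals) == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_matches_erf_oracle(self):
        sd = 0.3
        pos = np.arange(-2.0, 2.001, 0.01)
        vals = np.exp(-(pos**2) / (2 * sd**2))
        expected = sd * np.sqrt(2 * np.pi) * special.erf(2.0 / (sd * np.sqrt(2)))
        assert pr.profile_auc(pos, vals) == pytest.approx(expected, rel=0.01)


class TestSignalLength:
    def test_rectangular_pulse_exact(self):
        pos = np.arange(0.0, 4.001, 0.01)
        vals = ((pos >= 1.0) & (pos < 2.2)).astype(float)
        # interpolated crossings sit half a sample outside the run
        assert pr.signal_length(pos, vals) == pytest.approx(1.2, abs=0.011)

    def test_zero_signal(self):
        pos = np.arange(0.0, 4.001, 0.01)
        assert pr.signal_length(pos, np.zeros(pos.size)) == 0.0

    def test_generated_length_ratio(self):
        kw = dict(marker_mode="tip", noise_sd=0.0, n_profiles=1, seed=0,
                  length_cv=0.0, center_jitter_sd=0.0)
        p10 = syn.gen_line_profiles(micro_length=1.0, **kw)[0]
        p06 = syn.gen_line_profiles(micro_length=0.6, **kw)[0]
        l10 = pr.signal_length(p10.positions, p10.ref_intensity)
        l06 = pr.signal_length(p06.positions, p06.ref_intensity)
        assert abs(l06 / l10 - 0.6) < 0.06


class TestAucPerLength:
    def test_basic_and_linearity(self):
        assert pr.auc_per_length(1.5, 1.5) == 1.0
        assert pr.auc_per_length(3.0, 1.5) == 2.0 * pr.auc_per_length(1.5, 1.5)

    def test_zero_length_missing(self):
        assert np.isnan(pr.auc_per_length(1.0, 0.0))

    def test_length_normalization_eliminates_amplitude_difference(self):
        """Halving microvillus length ~halves the AUC but leaves AUC per unit
        signal length unchanged — shortened microvilli carry the same
        protein density."""
        kw = dict(marker_mode="tip", noise_sd=0.0, n_profiles=1, seed=0,
                  length_cv=0.0, center_jitter_sd=0.0)
        p_long = syn.gen_line_profiles(micro_length=1.0, **kw)[0]
        p_short = syn.gen_line_profiles(micro_length=0.5, **kw)[0]
        auc_l = pr.profile_auc(p_long.positions, p_long.ref_intensity)
        auc_s = pr.profile_auc(p_short.positions, p_short.ref_intensity)
        len_l = pr.signal_length(p_long.positions, p_long.ref_intensity)
        len_s = pr.signal_length(p_short.positions, p_short.ref_intensity)
        assert abs(auc_l / auc_s - 2.0) < 0.2
        ratio = pr.auc_per_length(auc_l, len_l) / pr.auc_per_length(auc_s, len_s)
        assert abs(ratio - 1.0) < 0.10
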