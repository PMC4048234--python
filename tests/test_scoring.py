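import numpy as np
import pytest
from hypothesis import given, strategies as st

import isletquant as iq
from isletquant.errors import ParameterError

from conftest import mixture_image, wcss_oracle_stained


def _nucleus_set(shape, centroids=(), mask=None):
    cent = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if mask is None:
        mask = np.zeros(shape, dtype=bool)
    return iq.NucleusSet(centroids=cent, nuclei_mask=mask)


def _stain_map(mask):
    return iq.StainMap(stained_mask=mask, threshold=0.5, cluster_centers=(0.1, 0.9))


class TestSeparateStaining:
    def test_two_point_histogram(self):
        vals = np.concatenate([np.full(1000, 0.1), np.full(500, 0.9)])
        img = vals.reshape(30, 50)
        sm = iq.separate_staining(img)
        assert not sm.degenerate
        assert sm.cluster_centers[0] == pytest.approx(0.1, abs=1 / 256)
        assert sm.cluster_centers[1] == pytest.approx(0.9, abs=1 / 256)
        assert sm.stained_mask.sum() == 500
        assert 0.1 < sm.threshold < 0.9

    def test_symmetric_mixture_threshold_near_midpoint(self):
        rng = np.random.default_rng(77)
        vals = np.concatenate(
            [rng.normal(0.2, 0.05, 25000), rng.normal(0.8, 0.05, 25000)]
        )
        img = np.clip(vals, 0, 1).reshape(200, 250)
        sm = iq.separate_staining(img, histogram_bins=256)
        assert sm.threshold == pytest.approx(0.5, abs=1 / 256)

    def test_constant_image_is_degenerate(self):
        sm = iq.separate_staining(np.full((20, 20), 0.5))
        assert sm.degenerate
        assert not sm.stained_mask.any()

    def test_threshold_consistency_invariant(self):
        img = mixture_image(3)
        sm = iq.separate_staining(img)
        np.testing.assert_array_equal(sm.stained_mask, img >= sm.threshold)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_wcss_oracle(self, seed):
        img = mixture_image(20_000 + seed)
        sm = iq.separate_staining(img)
        np.testing.assert_array_equal(sm.stained_mask, wcss_oracle_stained(img))


class TestClassifyCells:
    def _maps(self, shape, n488, n555, at):
        m488 = np.zeros(shape, dtype=bool)
        m555 = np.zeros(shape, dtype=bool)
        r, c = at
        m488.ravel()[:0] = False
        # fill pixels row-wise near the centroid
        ii, jj = np.mgrid[: shape[0], : shape[1]]
        order = np.argsort((ii - r) ** 2 + (jj - c) ** 2, axis=None, kind="stable")
        m488.ravel()[order[:n488]] = True
        m555.ravel()[order[:n555]] = True
        return _stain_map(m488), _stain_map(m555)

    def test_majority_labels_beta(self):
        shape = (30, 30)
        m488, m555 = self._maps(shape, 40, 5, (15, 15))
        cells = iq.classify_cells(_nucleus_set(shape, [(15, 15)]), m488, m555, 8)
        assert cells.labels == (iq.BETA,)
        assert cells.counts488[0] > cells.counts555[0]

    def test_no_evidence_is_unclassified(self):
        shape = (30, 30)
        m488, m555 = self._maps(shape, 0, 0, (15, 15))
        cells = iq.classify_cells(_nucleus_set(shape, [(15, 15)]), m488, m555, 8)
        assert cells.labels == (iq.UNCLASSIFIED,)

    def test_tie_is_unclassified(self):
        shape = (30, 30)
        m488, m555 = self._maps(shape, 17, 17, (15, 15))
        cells = iq.classify_cells(_nucleus_set(shape, [(15, 15)]), m488, m555, 8)
        assert cells.labels == (iq.UNCLASSIFIED,)

    def test_label_counts_conserve(self, noisy_islet):
        _, stack, islet, _ = noisy_islet
        nuc = iq.detect_nuclei(stack.dapi, islet)
        cells = iq.classify_cells(
            nuc,
            iq.separate_staining(stack.target488),
            iq.separate_staining(stack.counter555),
            7.5,
        )
        assert cells.n_beta + cells.n_alpha + cells.n_unclassified == nuc.n

    def test_synthetic_labels_match_ground_truth(self):
        params = iq.SynthParams(seed=41, n_nuclei=15, beta_fraction=10 / 15,
                                noise_sd=0.0, illumination_gradient=0.0)
        stack, islet, truth = iq.generate_islet(params)
        nuc = iq.detect_nuclei(stack.dapi, islet)
        cells = iq.classify_cells(
            nuc,
            iq.separate_staining(stack.target488),
            iq.separate_staining(stack.counter555),
            7.5,
        )
        from scipy.spatial import cKDTree
        d, idx = cKDTree(truth.nuclei_centers).query(nuc.centroids)
        ok = d <= 2 * params.nucleus_radius
        correct = sum(
            1 for k in range(nuc.n) if ok[k] and cells.labels[k] == truth.cell_class[idx[k]]
        )
        assert correct / ok.sum() >= 0.95


class TestAreaScore:
    def _fixture(self):
        islet = np.zeros((40, 40), dtype=bool)
        islet[:25, :] = True  # 1000 px
        nmask = np.zeros((40, 40), dtype=bool)
        nmask[:5, :] = True   # 200 nucleus px, inside the islet
        stained = np.zeros((40, 40), dtype=bool)
        stained[:5, :] = True          # all nucleus px stained
        stained[5:15, :] = True        # 400 further non-nuclear stained px
        return _stain_map(stained), iq.IsletMask(islet), _nucleus_set((40, 40), [(2, 2)], nmask)

    def test_direct_pixel_arithmetic(self):
        stain, islet, nuclei = self._fixture()
        score, frac = iq.area_score(stain, islet, nuclei)
        assert frac == pytest.approx(0.4)
        assert score == pytest.approx(1.2)

    def test_alternative_denominator_excludes_nuclei(self):
        stain, islet, nuclei = self._fixture()
        score, frac = iq.area_score(stain, islet, nuclei,
                                    denominator="islet_minus_nuclei")
        assert frac == pytest.approx(400 / 800)
        assert score == pytest.approx(1.5)

    def test_bounds(self):
        islet = iq.IsletMask(np.ones((10, 10), dtype=bool))
        full = _stain_map(np.ones((10, 10), dtype=bool))
        none = _stain_map(np.zeros((10, 10), dtype=bool))
        assert iq.area_score(full, islet)[0] == 3.0
        assert iq.area_score(none, islet)[0] == 0.0

    def test_monotone_in_added_stained_pixels(self):
        islet = iq.IsletMask(np.ones((20, 20), dtype=bool))
        rng = np.random.default_rng(8)
        mask = rng.random((20, 20)) < 0.2
        base, _ = iq.area_score(_stain_map(mask), islet)
        grown = mask.copy()
        grown[np.unravel_index(np.flatnonzero(~mask)[:10], mask.shape)] = True
        more, _ = iq.area_score(_stain_map(grown), islet)
        assert more >= base

    def test_invariant_to_changes_outside_islet(self):
        islet = np.zeros((20, 20), dtype=bool)
        islet[5:15, 5:15] = True
        inner = np.zeros((20, 20), dtype=bool)
        inner[6:10, 6:10] = True
        outer = inner.copy()
        outer[0:3, 0:3] = True  # extra stained pixels outside the islet
        im = iq.IsletMask(islet)
        assert iq.area_score(_stain_map(inner), im) == iq.area_score(_stain_map(outer), im)

    def test_score_is_three_times_fraction(self, noisy_islet):
        _, stack, islet, _ = noisy_islet
        sm = iq.separate_staining(stack.target488)
        score, frac = iq.area_score(sm, islet)
        assert score == 3.0 * frac


class TestSizeAndDensity:
    def test_islet_size_px_and_um2(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:6, 2:6] = True
        islet = iq.IsletMask(mask)
        assert iq.islet_size(islet) == (16, None)
        px, um2 = iq.islet_size(islet, pixel_size=0.5)
        assert (px, um2) == (16, pytest.approx(4.0))
        with pytest.raises(ParameterError):
            iq.islet_size(islet, pixel_size=-1)

    def test_beta_density_units(self):
        islet = np.zeros((40, 40), dtype=bool)
        islet[:25, :] = True  # 1000 px
        cells = iq.CellClassification(
            labels=(iq.BETA,) * 10, counts488=np.ones(10), counts555=np.zeros(10),
            patch_radius=5.0,
        )
        dens, per_mm2 = iq.beta_density(cells, iq.IsletMask(islet))
        assert dens == pytest.approx(100.0)  # per 10^4 px²
        assert per_mm2 is None
        _, per_mm2 = iq.beta_density(cells, iq.IsletMask(islet), pixel_size=1.0)
        assert per_mm2 == pytest.approx(10_000.0)  # 10 cells / 1000 µm² → per mm²

    def test_zero_beta_cells(self):
        islet = iq.IsletMask(np.ones((10, 10), dtype=bool))
        cells = iq.CellClassification(labels=(), counts488=[], counts555=[],
                                      patch_radius=5.0)
        assert iq.beta_density(cells, islet)[0] == 0.0


class TestManualScoreSurrogate:
    @pytest.mark.parametrize(
        "level,frac,expected",
        [(3, 1.0, 3.0), (0, 0.7, 0.0), (2, 0.6, 1.25), (1, 0.5, 0.5), (3, 0.33, 1.0)],
    )
    def test_known_values(self, level, frac, expected):
        assert iq.manual_score_surrogate(level, frac) == expected

    @given(level=st.integers(0, 3), frac=st.floats(0.0, 1.0))
    def test_quantised_to_quarter_steps_in_range(self, level, frac):
        s = iq.manual_score_surrogate(level, frac)
        assert 0.0 <= s <= 3.0
        assert (s * 4) == int(s * 4)
        assert abs(s - level * frac) <= 0.125 + 1e-9

    def test_out_of_range_inputs_raise(self):
        with pytest.raises(ParameterError):
            iq.manual_score_surrogate(4, 0.5)
        with pytest.raises(ParameterError):
            iq.manual_score_surrogate(2, 1.5)


class TestScoreIslet:
    def test_recovers_true_fraction_cleanly(self):
        params = iq.SynthParams(seed=51, noise_sd=0.0, illumination_gradient=0.0,
                                target_stained_fraction=0.35)
        stack, islet, truth = iq.generate_islet(params)
        feats = iq.score_islet(stack, islet)
        assert feats.area_score == pytest.approx(3 * truth.true_stained_fraction,
                                                 abs=1e-12)

    def test_all_background_islet_scores_zero(self):
        stack = iq.ChannelStack(
            dapi=np.full((30, 30), 0.1),
            target488=np.full((30, 30), 0.1),
            counter555=np.full((30, 30), 0.1),
        )
        feats = iq.score_islet(stack, iq.IsletMask(np.ones((30, 30), dtype=bool)))
        assert feats.area_score == 0.0
        assert feats.n_beta == 0

    def test_determinism(self, noisy_islet):
        _, stack, islet, _ = noisy_islet
        assert iq.score_islet(stack, islet) == iq.score_islet(stack, islet)

    def test_mismatched_mask_raises(self, noisy_islet):
        _, stack, _, _ = noisy_islet
        with pytest.raises(ParameterError):
            iq.score_islet(stack, iq.IsletMask(np.ones((10, 10), dtype=bool)))
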