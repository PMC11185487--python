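import numpy as np
import pytest

from sersev import (Spectrum, SpectrumSet, WavenumberGrid, fit_lda,
                    overlap_rate_groups, overlap_rate_hull2d,
                    overlap_rate_range1d, pooled_fraction_overlap, transform)
from sersev.exceptions import GridError, LDAError

GRID = WavenumberGrid(564.0, 1681.0, 1117)
SMALL = WavenumberGrid(564.0, 1681.0, 40)


def _cloud(rng, grid, mean, n, sd=1.0, **meta):
    return [Spectrum(grid, mean + rng.normal(0, sd, grid.n_points), dict(meta))
            for _ in range(n)]


def _two_cloud_set(sep=10.0, n=50, seed=0, grid=GRID):
    rng = np.random.default_rng(seed)
    m1 = np.zeros(grid.n_points)
    m2 = np.zeros(grid.n_points)
    m2[5] = sep  # separated along one axis by sep * sd
    spectra = _cloud(rng, grid, m1, n) + _cloud(rng, grid, m2, n)
    labels = ["a"] * n + ["b"] * n
    return SpectrumSet(spectra), labels


class TestFitLDA:
    def test_separated_clouds_no_overlap(self):
        sset, labels = _two_cloud_set(sep=10.0)
        emb = fit_lda(sset, labels)
        assert emb.dims == 1
        a = emb.group_scores("a")[:, 0]
        b = emb.group_scores("b")[:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            overlap_rate_range1d(a, b) == 0.0

    def test_shuffled_labels_shrink_separation(self):
        sset, labels = _two_cloud_set(sep=10.0, grid=SMALL)
        emb = fit_lda(sset, labels)
        sep_true = abs(emb.class_means["a"][0] - emb.class_means["b"][0]) \
            / emb.scores[:, 0].std()
        rng = np.random.default_rng(1)
        shuffled = list(labels)
        rng.shuffle(shuffled)
        emb2 = fit_lda(sset, shuffled)
        sep_shuf = abs(emb2.class_means["a"][0] - emb2.class_means["b"][0]) \
            / emb2.scores[:, 0].std()
        assert sep_shuf < sep_true

    def test_three_groups_give_two_dims(self):
        rng = np.random.default_rng(2)
        spectra, labels = [], []
        for k in range(3):
            m = np.zeros(SMALL.n_points)
            m[k] = 8.0
            spectra += _cloud(rng, SMALL, m, 10)
            labels += [f"g{k}"] * 10
        emb = fit_lda(SpectrumSet(spectra), labels)
        assert emb.dims == 2
        assert emb.scores.shape == (30, 2)

    def test_single_group_rejected(self):
        sset, _ = _two_cloud_set(grid=SMALL, n=5)
        with pytest.raises(LDAError):
            fit_lda(sset, ["a"] * len(sset))

    def test_small_group_rejected(self):
        sset, labels = _two_cloud_set(grid=SMALL, n=5)
        labels = list(labels)
        labels[0] = "c"  # group with a single member
        with pytest.raises(LDAError, match="fewer than 2"):
            fit_lda(sset, labels)


class TestTransform:
    def test_training_set_reproduced(self):
        sset, labels = _two_cloud_set(grid=SMALL)
        emb = fit_lda(sset, labels)
        assert np.allclose(transform(emb, sset), emb.scores, atol=1e-9)

    def test_class_mean_spectrum_maps_to_centroid(self):
        sset, labels = _two_cloud_set(grid=SMALL, n=100)
        emb = fit_lda(sset, labels)
        X = sset.intensity_matrix
        mean_a = X[np.array(labels) == "a"].mean(axis=0)
        score = transform(emb, SpectrumSet([Spectrum(SMALL, mean_a)]))
        assert np.allclose(score[0], emb.class_means["a"], atol=1e-8)

    def test_zero_spectrum_finite(self):
        sset, labels = _two_cloud_set(grid=SMALL)
        emb = fit_lda(sset, labels)
        score = transform(emb, SpectrumSet([Spectrum(SMALL, np.zeros(SMALL.n_points))]))
        assert np.all(np.isfinite(score))

    def test_grid_mismatch_rejected(self):
        sset, labels = _two_cloud_set(grid=SMALL)
        emb = fit_lda(sset, labels)
        other = SpectrumSet([Spectrum(GRID, np.zeros(GRID.n_points))])
        with pytest.raises(GridError):
            transform(emb, other)

    def test_deterministic_sign_convention(self):
        sset, labels = _two_cloud_set(grid=SMALL)
        e1 = fit_lda(sset, labels)
        e2 = fit_lda(sset, labels)
        assert np.array_equal(e1.scores, e2.scores)
        nz = np.flatnonzero(np.abs(e1.projection[0]) > 1e-12)
        assert e1.projection[0][nz[0]] > 0


class TestRange1D:
    def test_identity_100(self):
        a = np.array([0.0, 1.0, 2.0])
        assert overlap_rate_range1d(a, a) == 100.0

    def test_disjoint_0(self):
        assert overlap_rate_range1d(np.array([5.0, 6.0]), np.array([0.0, 1.0])) == 0.0

    def test_hand_enumeration_half(self):
        a = np.array([0.0, 1.0, 2.0, 3.0])
        b = np.array([0.5, 2.5])
        assert overlap_rate_range1d(a, b) == 50.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 50), rng.normal(0.5, 1, 50)
        base = overlap_rate_range1d(a, b)
        assert overlap_rate_range1d(3.0 * a + 2.0, 3.0 * b + 2.0) == base

    def test_empty_error(self):
        with pytest.raises(LDAError):
            overlap_rate_range1d(np.array([]), np.array([1.0]))


class TestHull2D:
    def test_disjoint_clusters_zero(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (40, 2))
        b = rng.normal(50, 1, (40, 2))
        assert overlap_rate_hull2d(a, b) == 0.0
        assert overlap_rate_hull2d(b, a) == 0.0

    def test_duplicated_group_is_100(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 1, (10, 2))
        assert overlap_rate_hull2d(pts, pts.copy()) == 100.0

    def test_hull_needs_three_points(self):
        a = np.zeros((5, 2))
        with pytest.raises(LDAError):
            overlap_rate_hull2d(a, np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_degenerate_collinear_hull(self):
        seg = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        probes = np.array([[1.0, 0.0], [1.0, 0.5], [3.0, 0.0]])
        assert overlap_rate_hull2d(probes, seg) == pytest.approx(100.0 / 3.0)

    def test_planted_overlap_recovered(self):
        # hull group: square [0,1]^2; probe group: 10 % planted inside
        rng = np.random.default_rng(6)
        hull_pts = rng.uniform(0, 1, (300, 2))
        n, frac = 500, 0.10
        inside = rng.uniform(0.3, 0.7, (n, 2))
        outside = rng.uniform(5, 6, (n, 2))
        pick = rng.random(n) < frac
        probes = np.where(pick[:, None], inside, outside)
        got = overlap_rate_hull2d(probes, hull_pts)
        assert abs(got - 100 * frac) <= 4.0


class TestOverlapGroups:
    def _embedding(self, seed=7, sep=8.0):
        rng = np.random.default_rng(seed)
        spectra, labels = [], []
        for k in range(3):
            m = np.zeros(SMALL.n_points)
            m[k] = sep
            spectra += _cloud(rng, SMALL, m, 20, fraction=f"F{7 + k}")
            labels += [f"F{7 + k}"] * 20
        return fit_lda(SpectrumSet(spectra), labels)

    def test_well_separated_all_rules_zero(self):
        emb = self._embedding(sep=60.0)  # >= 6 sigma separation in scores
        for rule in ("hull2d", "classify"):
            rep = overlap_rate_groups(emb, rule)
            assert all(v == 0.0 for v in rep.pairwise.values())

    def test_classify_rows_sum_le_100(self):
        emb = self._embedding(sep=2.0)  # heavy mixing
        rep = overlap_rate_groups(emb, "classify")
        for gi in emb.groups:
            total = sum(v for (a, b), v in rep.pairwise.items() if a == gi)
            assert total <= 100.0 + 1e-9

    def test_report_percent_bounds(self):
        rep = overlap_rate_groups(self._embedding(), "hull2d")
        for v in rep.pairwise.values():
            assert 0.0 <= v <= 100.0


class TestPooled:
    def _sets(self, shifts, seed=8, n=30, sd=1.0):
        rng = np.random.default_rng(seed)
        ref, test = [], []
        for k, frac in enumerate(("F7", "F8", "F9")):
            m = np.zeros(SMALL.n_points)
            m[k] = 5.0
            ref += _cloud(rng, SMALL, m, n, sd, fraction=frac, cell_line="ref")
            m2 = m.copy()
            m2[10] = shifts[k]
            test += _cloud(rng, SMALL, m2, n, sd, fraction=frac, cell_line="test")
        return SpectrumSet(ref), SpectrumSet(test)

    def test_identical_populations_fully_overlap(self):
        ref, _ = self._sets([0.0, 0.0, 0.0])
        rep = pooled_fraction_overlap(ref, ref)
        assert all(v >= 95.0 for v in rep.per_fraction.values())

    def test_planted_shift_ordering_preserved(self):
        # stronger cell-type shift => less overlap with the reference range
        ref, test = self._sets([12.0, 8.0, 4.0])
        rep = pooled_fraction_overlap(ref, test)
        assert rep.per_fraction["F7"] <= rep.per_fraction["F8"] \
            <= rep.per_fraction["F9"]
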