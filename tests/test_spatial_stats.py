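"""Moran's I, Mantel machinery and the Dutilleul correction, checked
against brute-force oracles, exhaustive enumeration and R (ape/vegan)."""

import shutil
import subprocess
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betageo.data_model import DistanceMatrix, ValidationError
from betageo.spatial_stats import (
    inverse_distance_weights,
    mantel_test,
    modified_ttest,
    morans_i,
    partial_correlation,
    partial_mantel_test,
    pearson_two_sided_p,
)
from conftest import random_distance_matrix


def brute_force_moran(x, w):
    """Literal double-sum evaluation of Moran's I."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / w.sum()) * num / (z**2).sum()


class TestMoran:
    def test_expected_value_minus_one_over_n_minus_one(self):
        rng = np.random.default_rng(0)
        w = rng.random((17, 17))
        np.fill_diagonal(w, 0)
        res = morans_i(rng.random(17), w)
        assert res.expected_i == pytest.approx(-1 / 16)
        assert res.expected_i == -0.0625

    def test_collinear_inverse_distance_case_matches_double_sum(self):
        pts = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.abs(pts[:, None] - pts[None, :])
        with np.errstate(divide="ignore"):
            w = np.where(d > 0, 1 / d, 0.0)
        res = morans_i([1.0, 2.0, 3.0, 4.0], w)
        assert res.observed_i == pytest.approx(
            brute_force_moran([1, 2, 3, 4], w))

    @given(st.integers(0, 2**30 - 1), st.integers(4, 6))
    def test_matches_brute_force_oracle_small_n(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        w = rng.random((n, n))
        np.fill_diagonal(w, 0)
        res = morans_i(x, w)
        assert res.observed_i == pytest.approx(brute_force_moran(x, w),
                                               abs=1e-12)
        assert 0 <= res.p_value <= 1

    def test_constant_values_rejected(self):
        w = 1 - np.eye(5)
        with pytest.raises(ValidationError, match="constant"):
            morans_i(np.ones(5), w)

    def test_negative_weight_rejected(self):
        w = 1 - np.eye(5)
        w[0, 1] = -0.5
        with pytest.raises(ValidationError, match="negative"):
            morans_i(np.arange(5.0), w)

    def test_agrees_with_r_ape(self, tmp_path):
        """Cross-check statistic and randomization sd against ape::Moran.I."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; oracle cannot run")
        rng = np.random.default_rng(7)
        x = rng.normal(size=8)
        w = rng.random((8, 8))
        np.fill_diagonal(w, 0)
        w = w / w.sum(axis=1, keepdims=True)  # ape row-normalises internally
        np.savetxt(tmp_path / "x.csv", x, delimiter=",")
        np.savetxt(tmp_path / "w.csv", w, delimiter=",")
        out = subprocess.run(
            ["Rscript", "-e",
             f'x <- scan("{tmp_path}/x.csv"); '
             f'w <- as.matrix(read.csv("{tmp_path}/w.csv", header=FALSE)); '
             'r <- ape::Moran.I(x, w); '
             'cat(r$observed, r$sd, r$p.value)'],
            capture_output=True, text=True, check=True)
        obs_r, sd_r, p_r = map(float, out.stdout.split())
        res = morans_i(x, w, alternative="two_sided")
        # R's cat() prints 7 significant digits
        assert res.observed_i == pytest.approx(obs_r, rel=1e-6)
        assert res.sd_i == pytest.approx(sd_r, rel=1e-6)
        assert res.p_value == pytest.approx(p_r, rel=1e-6)


class TestMantel:
    def test_perfect_concordance(self):
        # enough objects that a random draw of the identity permutation
        # (which ties r = 1) is vanishingly unlikely
        rng = np.random.default_rng(42)
        d = random_distance_matrix(rng, [f"r{i}" for i in range(12)])
        res = mantel_test(d, d, n_permutations=99, seed=0)
        assert res.statistic_r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_p_matches_exhaustive_enumeration_n4(self):
        """999 random permutations agree with all 4! = 24 relabelings."""
        rng = np.random.default_rng(11)
        a = random_distance_matrix(rng, list("abcd"))
        b = random_distance_matrix(rng, list("abcd"))
        iu = np.triu_indices(4, k=1)
        va = a.values[iu]
        r_obs = np.corrcoef(va, b.values[iu])[0, 1]
        count = 0
        for perm in permutations(range(4)):
            vp = b.values[np.ix_(perm, perm)][iu]
            count += np.corrcoef(va, vp)[0, 1] >= r_obs - 1e-12
        exact_p = count / 24  # every relabeling equally likely
        res = mantel_test(a, b, n_permutations=999, seed=3)
        assert res.statistic_r == pytest.approx(r_obs)
        # Monte-Carlo error of 999 draws around the enumerated value
        assert res.p_value == pytest.approx(exact_p, abs=0.06)

    def test_r_invariant_to_common_relabeling(self, small_regions):
        from betageo.data_model import (
            climate_distance_matrix,
            geographic_distance_matrix,
        )

        geo = geographic_distance_matrix(small_regions)
        clim = climate_distance_matrix(small_regions)
        r1 = mantel_test(geo, clim, 9, seed=0).statistic_r
        order = geo.labels[::-1]
        r2 = mantel_test(geo.align(order), clim.align(order), 9,
                         seed=0).statistic_r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_label_mismatch_rejected(self, small_regions):
        from betageo.data_model import geographic_distance_matrix

        geo = geographic_distance_matrix(small_regions)
        other = DistanceMatrix(["w", "x", "y", "z"], geo.values)
        with pytest.raises(ValidationError, match="label"):
            mantel_test(geo, other)

    def test_agrees_with_r_vegan(self, tmp_path):
        """Statistic cross-checked against vegan::mantel."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; oracle cannot run")
        rng = np.random.default_rng(5)
        a = random_distance_matrix(rng, [f"r{i}" for i in range(7)])
        b = random_distance_matrix(rng, [f"r{i}" for i in range(7)])
        np.savetxt(tmp_path / "a.csv", a.values, delimiter=",")
        np.savetxt(tmp_path / "b.csv", b.values, delimiter=",")
        out = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(vegan)); '
             f'a <- as.dist(as.matrix(read.csv("{tmp_path}/a.csv", header=FALSE))); '
             f'b <- as.dist(as.matrix(read.csv("{tmp_path}/b.csv", header=FALSE))); '
             'cat(mantel(a, b, permutations=9)$statistic)'],
            capture_output=True, text=True, check=True)
        assert mantel_test(a, b, 9, seed=0).statistic_r == pytest.approx(
            float(out.stdout), abs=1e-8)


class TestPartialMantel:
    def test_closed_form_partial_correlation(self):
        assert partial_correlation(0.8, 0.5, 0.5) == pytest.approx(
            0.55 / 0.75)
        assert partial_correlation(0.8, 0.5, 0.5) == pytest.approx(0.73333,
                                                                   abs=1e-5)

    def test_b_equals_c_collapses_to_zero(self):
        rng = np.random.default_rng(2)
        a = random_distance_matrix(rng, list("abcde"))
        b = random_distance_matrix(rng, list("abcde"))
        res = partial_mantel_test(a, b, b, n_permutations=49, seed=0)
        assert res.statistic_r == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_control_rejected(self):
        rng = np.random.default_rng(3)
        a = random_distance_matrix(rng, list("abcde"))
        b = random_distance_matrix(rng, list("abcde"))
        with pytest.raises(ValidationError, match="degenerate"):
            partial_mantel_test(a, b, a)

    def test_add_one_estimator_floor(self):
        rng = np.random.default_rng(4)
        c = random_distance_matrix(rng, list("abcdef"))
        a = random_distance_matrix(rng, list("abcdef"))
        res = partial_mantel_test(a, a, c, n_permutations=99, seed=1)
        assert res.statistic_r == pytest.approx(1.0)
        assert res.p_value >= 1 / 100


class TestModifiedTTest:
    def test_closed_form_t_for_r_0607_n14(self):
        # t = r sqrt(n-2)/sqrt(1-r^2) with 12 df
        assert pearson_two_sided_p(0.607, 14) == pytest.approx(0.021,
                                                               abs=5e-4)

    def test_white_noise_effective_n_near_n(self):
        """Spatially independent variables lose almost no information."""
        rng = np.random.default_rng(10)
        diffs, ess_ratio = [], []
        for _ in range(200):
            n = 30
            coords = np.column_stack(
                [rng.uniform(35, 45, n), rng.uniform(5, 15, n)])
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = modified_ttest(x, y, coords)
            diffs.append(abs(res.corrected_p - res.classical_p))
            ess_ratio.append(res.effective_sample_size / n)
        assert np.median(diffs) < 0.05
        assert np.median(ess_ratio) > 0.7

    def test_shared_gradient_shrinks_effective_n(self):
        """A smooth common trend must cost degrees of freedom."""
        rng = np.random.default_rng(20)
        smaller, larger_p = 0, 0
        for _ in range(50):
            n = 25
            lat = np.sort(rng.uniform(35, 45, n))
            coords = np.column_stack([lat, np.full(n, 10.0)])
            x = 3 * lat + rng.normal(0, 0.5, n)
            y = -2 * lat + rng.normal(0, 0.5, n)
            res = modified_ttest(x, y, coords)
            smaller += res.effective_sample_size < n
            larger_p += res.corrected_p >= res.classical_p - 1e-12
        assert smaller >= 45
        assert larger_p >= 45

    def test_corrected_p_not_below_classical_when_ess_shrinks(self):
        rng = np.random.default_rng(30)
        lat = np.sort(rng.uniform(35, 45, 20))
        coords = np.column_stack([lat, np.full(20, 10.0)])
        x = lat + rng.normal(0, 0.2, 20)
        y = lat + rng.normal(0, 0.2, 20)
        res = modified_ttest(x, y, coords)
        assert res.effective_sample_size <= 20
        if res.effective_sample_size < 20:
            assert res.corrected_p >= res.classical_p - 1e-12

    def test_constant_variable_rejected(self):
        coords = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValidationError, match="constant"):
            modified_ttest(np.ones(5), np.arange(5.0), coords)


class TestWeights:
    def test_inverse_distance_weights_zero_diagonal(self, small_regions):
        from betageo.data_model import geographic_distance_matrix

        w = inverse_distance_weights(geographic_distance_matrix(small_regions))
        assert np.diag(w).sum() == 0
        assert (w[~np.eye(4, dtype=bool)] > 0).all()
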