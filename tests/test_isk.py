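"""In silico kappa: pairwise statistics, oracles, group mean, bootstrap."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import iskappa as ik
from iskappa.isk import pairwise_kappas

from conftest import random_pir


def brute_force_kappa_max(a: int, b: int, n: int) -> float:
    """Max-agreement kappa over all 2x2 integer tables with margins
    (a, n-a) and (b, n-b): enumerate the joint both-positive cell."""
    best = -1
    for x in range(max(0, a + b - n), min(a, b) + 1):
        diag = x + (n - a - b + x)
        best = max(best, diag)
    p_o = best / n
    p_e = (a / n) * (b / n) + (1 - a / n) * (1 - b / n)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


def latent_interval_oracle(
    pir_a, pir_b, n_cases: int, rng: np.random.Generator
) -> float:
    """Simulate the ordered-category overlap directly: place cases
    uniformly on the latent [0,1] severity scale, categorize each by both
    raters' cumulative thresholds, and count agreements."""
    u = rng.random(n_cases)
    cat_a = np.searchsorted(np.cumsum(pir_a)[:-1], u)
    cat_b = np.searchsorted(np.cumsum(pir_b)[:-1], u)
    p_o = float(np.mean(cat_a == cat_b))
    p_e = float(np.dot(pir_a, pir_b))
    return (p_o - p_e) / (1 - p_e)


class TestMcoaPairKappa:
    def test_identical_margins_give_one(self):
        assert ik.mcoa_pair_kappa(0.3, 0.3) == pytest.approx(1.0)

    def test_hand_derived_value(self):
        # margins (2 of 10) vs (4 of 10): max diagonal 8, p_e 0.56
        assert ik.mcoa_pair_kappa(0.2, 0.4) == pytest.approx(
            (0.8 - 0.56) / 0.44
        )

    def test_fully_disjoint_margins_give_zero(self):
        # p_o_max = 0 but chance agreement is also 0, so kappa is exactly 0;
        # the max-agreement table never does worse than chance, so the
        # statistic is non-negative for every margin pair
        assert ik.mcoa_pair_kappa(0.0, 1.0) == pytest.approx(0.0)
        rng = np.random.default_rng(7)
        for _ in range(200):
            assert ik.mcoa_pair_kappa(rng.random(), rng.random()) >= 0.0

    def test_degenerate_same_pole_returns_one(self):
        assert ik.mcoa_pair_kappa(0.0, 0.0) == 1.0
        assert ik.mcoa_pair_kappa(1.0, 1.0) == 1.0

    def test_exhaustive_brute_force_small_n(self):
        # every margin pair on up to 12 cases
        for n in range(1, 13):
            for a, b in itertools.product(range(n + 1), repeat=2):
                expect = brute_force_kappa_max(a, b, n)
                got = ik.mcoa_pair_kappa(a / n, b / n)
                assert got == pytest.approx(expect, abs=1e-12), (a, b, n)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_symmetric(self, pa, pb):
        assert ik.mcoa_pair_kappa(pa, pb) == pytest.approx(
            ik.mcoa_pair_kappa(pb, pa)
        )


class TestOmecaPairKappa:
    def test_full_overlap_is_one(self):
        assert ik.omeca_pair_kappa([0.2, 0.5, 0.3], [0.2, 0.5, 0.3]) == 1.0

    def test_hand_derived_value(self):
        # overlaps 0.2 + 0.4 + 0.3 = 0.9, p_e = 0.35
        got = ik.omeca_pair_kappa([0.2, 0.5, 0.3], [0.3, 0.4, 0.3])
        assert got == pytest.approx((0.9 - 0.35) / 0.65)

    def test_disjoint_intervals(self):
        # opposite poles: zero overlap, but also zero chance agreement
        assert ik.omeca_pair_kappa([1, 0, 0], [0, 0, 1]) == pytest.approx(0.0)
        # shifted adjacent intervals: zero overlap with positive chance
        # agreement drives the statistic negative
        assert ik.omeca_pair_kappa([0.5, 0.5, 0], [0, 0.5, 0.5]) < 0

    def test_degenerate_shared_category_returns_one(self):
        assert ik.omeca_pair_kappa([0, 1, 0], [0, 1, 0]) == 1.0

    def test_invalid_vector_rejected(self):
        with pytest.raises(ValueError):
            ik.omeca_pair_kappa([0.5, 0.5, 0.5], [0.2, 0.5, 0.3])

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            pa, pb = random_pir(rng), random_pir(rng)
            mc = latent_interval_oracle(pa, pb, 200_000, rng)
            assert ik.omeca_pair_kappa(pa, pb) == pytest.approx(mc, abs=7e-3)

    def test_overlap_bounded_by_multicategory_kappa_max(self):
        # OMECA p_o <= sum_k min(pa_k, pb_k), so OMECA kappa <= Sim-Wright
        # multi-category kappa-maximum for every pair
        rng = np.random.default_rng(21)
        for _ in range(200):
            pa, pb = random_pir(rng), random_pir(rng)
            p_o_max = float(np.minimum(pa, pb).sum())
            p_e = float(pa @ pb)
            kmax = (p_o_max - p_e) / (1 - p_e)
            assert ik.omeca_pair_kappa(pa, pb) <= kmax + 1e-12

    def test_symmetric(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            pa, pb = random_pir(rng), random_pir(rng)
            assert ik.omeca_pair_kappa(pa, pb) == pytest.approx(
                ik.omeca_pair_kappa(pb, pa)
            )


class TestGroupIsk:
    def _profiles(self, rate_vectors, ns=None):
        ns = ns or [100] * len(rate_vectors)
        return [
            ik.RaterProfile(
                rater_id=f"P{i}",
                axis="G",
                counts=tuple(int(round(r * n)) for r in vec),
            )
            for i, (vec, n) in enumerate(zip(rate_vectors, ns))
        ]

    def test_identical_raters_give_one_under_both_assumptions(self):
        profs = self._profiles([[0.2, 0.5, 0.3]] * 10)
        assert ik.group_isk(profs, "OMECA") == pytest.approx(1.0)
        for k in (1, 2, 3):
            assert ik.group_isk(profs, "MCOA", score_level=k) == pytest.approx(1.0)

    def test_mean_over_pairs_composition(self):
        # binary level-1 rates 0.2, 0.2, 0.4: pairs (1, k(0.2,0.4) twice)
        profs = self._profiles(
            [[0.2, 0.8, 0.0], [0.2, 0.8, 0.0], [0.4, 0.6, 0.0]], ns=[10, 10, 10]
        )
        k24 = ik.mcoa_pair_kappa(0.2, 0.4)
        got = ik.group_isk(profs, "MCOA", score_level=1)
        assert got == pytest.approx((1 + 2 * k24) / 3)
        assert got == pytest.approx((1 + 2 * 0.5455) / 3, abs=1e-4)

    def test_group_matches_scalar_pairwise_mean(self, preset_profiles):
        for axis in ik.AXES:
            profs = preset_profiles[axis]
            pairs = pairwise_kappas(profs, "OMECA")
            assert ik.group_isk(profs, "OMECA") == pytest.approx(
                np.mean(list(pairs.values()))
            )
            pairs1 = pairwise_kappas(profs, "MCOA", score_level=1)
            assert ik.group_isk(profs, "MCOA", score_level=1) == pytest.approx(
                np.mean(list(pairs1.values()))
            )

    def test_invariant_to_rater_relabeling(self):
        vecs = [[0.1, 0.6, 0.3], [0.3, 0.3, 0.4], [0.2, 0.5, 0.3], [0.5, 0.25, 0.25]]
        a = ik.group_isk(self._profiles(vecs), "OMECA")
        b = ik.group_isk(self._profiles(vecs[::-1]), "OMECA")
        assert a == pytest.approx(b)

    def test_degenerate_profiles_excluded(self):
        profs = self._profiles([[0.2, 0.5, 0.3], [0.3, 0.4, 0.3]])
        profs.append(ik.RaterProfile(rater_id="Z", axis="G", counts=(0, 0, 0)))
        assert ik.group_isk(profs, "OMECA") == pytest.approx(
            ik.omeca_pair_kappa([0.2, 0.5, 0.3], [0.3, 0.4, 0.3])
        )
        with pytest.raises(ValueError):
            ik.group_isk(profs[1:2] + profs[2:], "OMECA")

    def test_volume_weighting_flag(self):
        vecs = [[0.2, 0.5, 0.3], [0.3, 0.4, 0.3], [0.1, 0.3, 0.6]]
        profs = self._profiles(vecs, ns=[10, 100, 400])
        unw = ik.group_isk(profs, "OMECA")
        wtd = ik.group_isk(profs, "OMECA", weighting="volume")
        pairs = pairwise_kappas(profs, "OMECA")
        w = {("P0", "P1"): 110, ("P0", "P2"): 410, ("P1", "P2"): 500}
        expect = sum(pairs[k] * w[k] for k in pairs) / sum(w.values())
        assert wtd == pytest.approx(expect)
        assert wtd != pytest.approx(unw)


class TestBootstrapCi:
    def test_deterministic_under_seed(self, preset_profiles):
        a = ik.bootstrap_ci(preset_profiles["G"], "OMECA", n_boot=300, seed=5)
        b = ik.bootstrap_ci(preset_profiles["G"], "OMECA", n_boot=300, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = ik.bootstrap_ci(preset_profiles["G"], "OMECA", n_boot=300, seed=6)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_ci_brackets_point_and_stays_in_range(self, preset_profiles):
        est = ik.bootstrap_ci(
            preset_profiles["NS"], "MCOA", score_level=1, n_boot=400, seed=1
        )
        assert est.ci_low <= est.statistic <= est.ci_high
        assert -1 <= est.ci_low and est.ci_high <= 1
        assert est.target == "NS1" and est.assumption == "MCOA"

    def test_identical_raters_tight_ci_near_one(self):
        profs = [
            ik.RaterProfile(rater_id=f"P{i}", axis="G", counts=(100, 250, 150))
            for i in range(6)
        ]
        est = ik.bootstrap_ci(profs, "OMECA", n_boot=400, seed=2)
        assert est.statistic == pytest.approx(1.0)
        assert est.ci_high <= 1.0
        assert est.ci_low > 0.85

    def test_small_n_boot_rejected(self, preset_profiles):
        with pytest.raises(ValueError):
            ik.bootstrap_ci(preset_profiles["G"], "OMECA", n_boot=50, seed=0)
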