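"""The four training losses and the hazard-to-risk transform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from daptsurv import (
    LossWeights,
    TimeGrid,
    bce_loss,
    cumulative_risk,
    pch_loss,
    reconstruction_loss,
    total_loss,
    triplet_loss,
)
from daptsurv.autodiff import Tensor
from daptsurv.objectives import piecewise_exponential_loglik


class TestReconstructionLoss:
    def test_identity_gives_zero(self):
        h = np.random.default_rng(0).normal(size=(3, 4))
        assert reconstruction_loss(h, h).item() == 0.0

    def test_hand_arithmetic(self):
        assert reconstruction_loss(
            np.array([1.0, 2.0]), np.array([0.0, 0.0])
        ).item() == pytest.approx(2.5)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        h, hr = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
        direct = float(np.mean((h - hr) ** 2))
        assert reconstruction_loss(h, hr).item() == pytest.approx(direct, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.ones((2, 3)), np.ones((3, 2)))

    def test_nonnegative_zero_iff_equal(self):
        rng = np.random.default_rng(2)
        h = rng.normal(size=(4, 4))
        perturbed = h + 1e-3
        assert reconstruction_loss(h, perturbed).item() > 0


class TestBCELoss:
    def test_uninformative_predictor_gives_log2(self):
        val = bce_loss(np.array([0.5, 0.5]), np.array([0, 1])).item()
        assert val == pytest.approx(math.log(2), abs=1e-12)

    def test_perfect_prediction_near_zero(self):
        val = bce_loss(np.array([0.0, 1.0]), np.array([0, 1])).item()
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.01, 0.99, size=20)
        y = rng.integers(0, 2, size=20).astype(float)
        direct = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert bce_loss(p, y).item() == pytest.approx(direct, abs=1e-12)

    def test_invalid_label_raises(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([2]))

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([]), np.array([]))


def brute_force_triplet(f: np.ndarray, y: np.ndarray, margin: float) -> float:
    """Per-anchor loop oracle: positive mean excludes the anchor, negative
    mean is the other-class average, hinge summed; singleton classes skip."""
    total = 0.0
    for i in range(len(f)):
        same = (y == y[i])
        same[i] = False
        if not same.any():
            continue
        pos = f[same].mean(axis=0)
        neg = f[y != y[i]].mean(axis=0)
        total += max(
            np.sum((f[i] - pos) ** 2) + margin - np.sum((f[i] - neg) ** 2), 0.0
        )
    return total


class TestTripletLoss:
    def test_satisfied_margin_gives_zero(self):
        # anchors sit exactly at their class mean; classes 10 apart, margin 1
        f = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0], [10.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        assert triplet_loss(f, y, margin=1.0).item() == 0.0

    def test_collapsed_embeddings_give_margin_per_anchor(self):
        f = np.zeros((6, 3))
        y = np.array([0, 0, 0, 1, 1, 1])
        beta = 0.7
        assert triplet_loss(f, y, margin=beta).item() == pytest.approx(6 * beta)

    def test_single_class_contributes_zero_without_raising(self):
        f = np.random.default_rng(0).normal(size=(4, 3))
        assert triplet_loss(f, np.zeros(4, dtype=int)).item() == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_anchor_loop(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=(6, 4))
        y = rng.integers(0, 2, size=6)
        margin = rng.uniform(0.0, 2.0)
        assert triplet_loss(f, y, margin).item() == pytest.approx(
            brute_force_triplet(f, y, margin), abs=1e-10
        )

    def test_invariant_to_rigid_translation(self):
        rng = np.random.default_rng(9)
        f = rng.normal(size=(8, 5))
        y = rng.integers(0, 2, size=8)
        shift = rng.normal(size=5)
        assert triplet_loss(f + shift, y).item() == pytest.approx(
            triplet_loss(f, y).item(), abs=1e-9
        )

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            triplet_loss(np.zeros((2, 2)), np.array([0, 1]), margin=-0.1)


class TestPCHLoss:
    def test_unit_case(self):
        """One patient, one unit interval, d=1, lambda=1:
        -(1*log 1 - 1*1 - 0)/1 = 1."""
        grid = TimeGrid((0.0, 1.0))
        val = pch_loss(np.array([[1.0]]), np.array([0.5]), np.array([1]), grid)
        assert val.item() == pytest.approx(1.0)

    def test_censored_patient_with_vanishing_hazard(self):
        grid = TimeGrid((0.0, 1.0))
        val = pch_loss(np.array([[1e-12]]), np.array([0.5]), np.array([0]), grid)
        assert val.item() == pytest.approx(0.0, abs=1e-10)

    def test_three_patient_fixture_term_by_term(self):
        """Spreadsheet-style recomputation of every term on the default grid
        (rho = 22, 30, 30, 90, 185)."""
        grid = TimeGrid()
        lam = np.array([
            [0.010, 0.002, 0.003, 0.001, 0.0005],   # t=25,  d=1, kappa=1
            [0.004, 0.003, 0.002, 0.001, 0.0020],   # t=75,  d=0, kappa=3
            [0.001, 0.001, 0.002, 0.003, 0.0040],   # t=365, d=1, kappa=5
        ])
        t = np.array([25.0, 75.0, 365.0])
        d = np.array([1, 0, 1])
        term1 = 1 * math.log(0.010) - 0.010 * 22 - 0.0
        term2 = 0.0 - 0.002 * 30 - (0.004 * 22 + 0.003 * 30)
        term3 = (1 * math.log(0.004) - 0.004 * 185
                 - (0.001 * 22 + 0.001 * 30 + 0.002 * 30 + 0.003 * 90))
        expected = -(term1 + term2 + term3) / 3
        assert pch_loss(lam, t, d, grid).item() == pytest.approx(expected, abs=1e-9)

    def test_exposure_mode_uses_within_interval_time(self):
        grid = TimeGrid((0.0, 10.0, 20.0))
        lam = np.array([[0.1, 0.2]])
        # t = 15 -> kappa=2; exposure 5 days in interval 2 plus full interval 1
        expected = -(math.log(0.2) - 0.2 * 5 - 0.1 * 10)
        val = pch_loss(lam, np.array([15.0]), np.array([1]), grid, mode="exposure")
        assert val.item() == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_exposure_mode_equals_piecewise_exponential_loglik(self, seed):
        """Exposure mode is the exact negative mean piecewise-exponential
        log-likelihood, checked against an independent closed-form calculator
        on random fixtures."""
        rng = np.random.default_rng(seed)
        grid = TimeGrid()
        n = rng.integers(2, 12)
        lam = rng.uniform(1e-4, 5e-2, size=(n, grid.n_intervals))
        t = rng.uniform(8.0, 365.0, size=n)
        d = rng.integers(0, 2, size=n)
        loss = pch_loss(lam, t, d, grid, mode="exposure").item()

        # independent oracle: Lambda(t) from interval overlaps, per patient
        ll = 0.0
        for i in range(n):
            cumhaz = 0.0
            for j in range(grid.n_intervals)            :
                lo, hi = grid.boundaries[j], grid.boundaries[j + 1]
                cumhaz += lam[i, j] * max(0.0, min(hi, t[i]) - lo)
            k = next(j for j in range(grid.n_intervals)
                     if grid.boundaries[j] < t[i] <= grid.boundaries[j + 1])
            ll += d[i] * math.log(lam[i, k]) - cumhaz
        assert loss == pytest.approx(-ll / n, abs=1e-9)

    def test_module_agreement_with_packaged_calculator(self):
        rng = np.random.default_rng(42)
        grid = TimeGrid()
        lam = rng.uniform(1e-4, 1e-2, size=(20, 5))
        t = rng.uniform(8.5, 365.0, size=20)
        d = rng.integers(0, 2, size=20)
        assert pch_loss(lam, t, d, grid, mode="exposure").item() == pytest.approx(
            -piecewise_exponential_loglik(lam, t, d, grid), abs=1e-12
        )

    def test_time_outside_grid_raises(self):
        grid = TimeGrid()
        with pytest.raises(Exception):
            pch_loss(np.ones((1, 5)), np.array([400.0]), np.array([1]), grid)


class TestCumulativeRisk:
    def test_zero_hazard_gives_zero_risk(self, grid):
        for t in (30.0, 180.0, 365.0):
            assert cumulative_risk(np.zeros(5), grid, t) == 0.0

    def test_log2_cumulative_hazard_gives_half(self):
        grid = TimeGrid((0.0, 100.0))
        lam = np.array([math.log(2) / 100.0])
        assert cumulative_risk(lam, grid, 100.0) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_fine_grid_numerical_integration(self, seed):
        rng = np.random.default_rng(seed)
        grid = TimeGrid()
        lam = rng.uniform(0.0, 0.02, size=5)
        t = rng.uniform(8.001, 365.0)
        # step-function hazard integrated on a fine mesh aligned with the
        # interval boundaries (midpoint rule is then exact per cell)
        mesh = np.union1d(np.linspace(8.0, t, 200_001),
                          [b for b in grid.boundaries if 8.0 <= b <= t])
        mids = (mesh[:-1] + mesh[1:]) / 2
        k = np.searchsorted(np.asarray(grid.boundaries), mids, side="left") - 1
        integral = np.sum(lam[k] * np.diff(mesh))
        expected = 1 - math.exp(-integral)
        assert cumulative_risk(lam, grid, t) == pytest.approx(expected, abs=1e-7)

    def test_exact_against_overlap_closed_form(self, grid):
        rng = np.random.default_rng(3)
        lam = rng.uniform(0.0, 0.02, size=5)
        for t in rng.uniform(8.001, 365.0, size=20):
            expected = 1 - math.exp(
                -sum(
                    lam[j] * max(0.0, min(grid.boundaries[j + 1], t) - grid.boundaries[j])
                    for j in range(5)
                )
            )
            assert cumulative_risk(lam, grid, t) == pytest.approx(expected, abs=1e-10)

    def test_nondecreasing_in_horizon_and_hazard(self, grid):
        rng = np.random.default_rng(4)
        lam = rng.uniform(0.0, 0.01, size=5)
        horizons = np.linspace(9.0, 365.0, 50)
        risks = [cumulative_risk(lam, grid, t) for t in horizons]
        assert np.all(np.diff(risks) >= 0)
        bumped = lam.copy()
        bumped[2] += 0.005
        assert cumulative_risk(bumped, grid, 365.0) > cumulative_risk(lam, grid, 365.0)

    def test_horizon_outside_grid_raises(self, grid):
        with pytest.raises(Exception):
            cumulative_risk(np.ones(5), grid, 366.0)


class TestTotalLoss:
    def test_published_ischemic_weights_arithmetic(self):
        w = LossWeights(a=0.3, b=0.14, c=0.95, triplet=0.0)
        assert total_loss(1.0, 1.0, 1.0, 1.0, w).item() == pytest.approx(1.39)

    def test_selector_weights(self):
        w = LossWeights(a=0.0, b=1.0, c=0.0, triplet=0.0)
        assert total_loss(7.0, 3.0, 11.0, 5.0, w).item() == 3.0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=8, max_size=8))
    def test_matches_dot_product(self, vals):
        comps, weights = vals[:4], vals[4:]
        if all(w == 0 for w in weights):
            weights = [1.0, 0.0, 0.0, 0.0]
        w = LossWeights(a=weights[0], b=weights[1], c=weights[2], triplet=weights[3])
        expected = float(np.dot(comps, weights))
        got = total_loss(comps[0], comps[1], comps[2], comps[3], w).item()
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(a=-0.1)
        with pytest.raises(ValueError):
            LossWeights(a=0, b=0, c=0, triplet=0)

    def test_monotone_in_each_component(self):
        w = LossWeights()
        base = total_loss(1.0, 1.0, 1.0, 1.0, w).item()
        assert total_loss(2.0, 1.0, 1.0, 1.0, w).item() >= base
        assert total_loss(1.0, 1.0, 2.0, 1.0, w).item() >= base
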