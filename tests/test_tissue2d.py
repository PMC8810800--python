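"""2D obstacle tissue: mask generators, Laplacian/conservation, and the
average-CV estimator against analytic fronts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bacnavsim.errors import ConductionBlockError, InvalidInputError
from bacnavsim.fixtures import circular_front, planar_front
from bacnavsim.models import get_model
from bacnavsim.tissue2d import (
    ActivationMap,
    TissueGrid,
    _edge_weights,
    average_cv_2d,
    generate_random_obstacles,
    generate_vertical_obstacles,
    laplacian,
    obstacle_count,
)


class TestRandomObstacles:
    def test_exact_count_at_fifteen_percent(self):
        mask = generate_random_obstacles(100, 100, 0.15, seed=3)
        assert mask.sum() == 1500

    def test_zero_fraction_empty_mask(self):
        assert generate_random_obstacles(100, 100, 0.0, seed=0).sum() == 0

    def test_determinism_and_seed_sensitivity(self):
        a = generate_random_obstacles(100, 100, 0.1, seed=11)
        b = generate_random_obstacles(100, 100, 0.1, seed=11)
        c = generate_random_obstacles(100, 100, 0.1, seed=12)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_fraction_rejected(self):
        for bad in (-0.01, 1.0, 1.5):
            with pytest.raises(InvalidInputError):
                generate_random_obstacles(10, 10, bad, seed=0)

    @settings(max_examples=30, deadline=None)
    @given(nx=st.integers(5, 40), ny=st.integers(5, 40),
           fraction=st.floats(0.0, 0.9), seed=st.integers(0, 2**31 - 1))
    def test_count_contract_for_any_fraction_and_seed(self, nx, ny,
                                                      fraction, seed):
        mask = generate_random_obstacles(nx, ny, fraction, seed)
        assert mask.sum() == obstacle_count(nx, ny, fraction)


class TestVerticalObstacles:
    def test_exact_count_at_twenty_percent(self):
        mask = generate_vertical_obstacles(100, 100, 0.20, 10, seed=3)
        assert mask.sum() == 2000

    def test_vertical_anisotropy_of_the_mask(self):
        """Strips make vertically adjacent obstacle pairs far more common
        than horizontally adjacent ones."""
        mask = generate_vertical_obstacles(100, 100, 0.10, 10, seed=5)
        vert_pairs = np.sum(mask[:-1, :] & mask[1:, :])
        horiz_pairs = np.sum(mask[:, :-1] & mask[:, 1:])
        assert vert_pairs > 3 * max(horiz_pairs, 1)

    def test_unit_strips_statistically_isotropic(self):
        """strip_length = 1 degenerates to the random mask: the column
        occupancy must be uniform by a chi-square test."""
        mask = generate_vertical_obstacles(200, 200, 0.10, 1, seed=9)
        col_counts = mask.sum(axis=0)
        chi2 = stats.chisquare(col_counts)
        assert chi2.pvalue > 0.01
        vert_pairs = np.sum(mask[:-1, :] & mask[1:, :])
        horiz_pairs = np.sum(mask[:, :-1] & mask[:, 1:])
        assert 0.5 < (vert_pairs + 1) / (horiz_pairs + 1) < 2.0

    def test_invalid_strip_length_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_vertical_obstacles(100, 100, 0.1, 0, seed=0)
        with pytest.raises(InvalidInputError):
            generate_vertical_obstacles(100, 100, 0.1, 101, seed=0)


class TestAverageCv:
    def _amap(self, tmap):
        return ActivationMap(tmap, np.zeros(tmap.shape, bool), (0, 0),
                             1.0, None)

    def test_planar_front_exact(self):
        cv = average_cv_2d(self._amap(planar_front(speed_cm_s=30.0)))
        assert cv == pytest.approx(30.0, rel=1e-9)

    def test_circular_front_within_three_percent(self):
        cv = average_cv_2d(self._amap(circular_front(speed_cm_s=25.0)))
        assert cv == pytest.approx(25.0, rel=0.03)

    def test_block_signal_when_under_activated(self):
        tmap = planar_front()
        amap = ActivationMap(tmap, np.zeros(tmap.shape, bool), (0, 0),
                             0.5, None)
        with pytest.raises(ConductionBlockError):
            average_cv_2d(amap)


def test_laplacian_conserves_charge_with_obstacles():
    """Severed connections must not leak: the Vm sum over non-obstacle
    nodes is invariant under pure diffusion."""
    rng = np.random.default_rng(1)
    mask = generate_random_obstacles(40, 40, 0.2, seed=2)
    v = np.where(mask, 0.0, rng.normal(size=(40, 40)))
    weights = _edge_weights(mask)
    total0 = v[~mask].sum()
    for _ in range(200):
        v = v + 0.1 * laplacian(v, weights)
    assert v[~mask].sum() == pytest.approx(total0, abs=1e-9)
    # obstacle nodes never receive anything
    assert np.all(v[mask] == 0.0)


def test_grid_refinement_changes_cv_less_than_five_percent():
    """Homogeneous 0.5 x 0.5 cm patch at dx and dx/2 (toy membrane, the
    designated PDE fixture): the average CV estimate moves < 5%."""
    from bacnavsim.tissue2d import StimPatch, run_tissue

    toy_state = get_model("toy").initial_state(1)[:, 0]
    cvs = {}
    for refine in (1, 2):
        nn = 50 * refine
        grid = TissueGrid(nx=nn, ny=nn, dx_cm=0.01 / refine,
                          species="toy", dt=0.01 / (refine * refine))
        amap, _ = run_tissue(
            grid, StimPatch(size=8 * refine, amplitude=60.0),
            initial_state=toy_state, t_max_ms=300.0)
        assert amap.activated_fraction == 1.0
        cvs[refine] = average_cv_2d(amap, dx_cm=grid.dx_cm,
                                    coarse_block=5 * refine)
    assert abs(cvs[1] - cvs[2]) / cvs[2] < 0.05


def test_tissue_grid_validation():
    with pytest.raises(InvalidInputError):
        TissueGrid(obstacle_mask=np.zeros((5, 7), bool))
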