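import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beetox.bioassay import BEHAVIOUR_CATEGORIES, CageObservation
from beetox.bsi import (
    BsiInputs,
    StressBand,
    bsi_from_cage,
    bsi_trajectory,
    classify_stress,
    compute_bsi,
    permutation_contrast,
)

from conftest import make_bioassay

ZEROS = (0.0,) * 7


class TestComputeBsi:
    @pytest.mark.parametrize(
        "ba", [ZEROS, (100.0,) * 7, (0, 50, 100, 25, 75, 10, 90)]
    )
    def test_all_dead_scores_exactly_one(self, ba):
        assert compute_bsi(100.0, ba) == 1.0

    def test_no_death_no_alteration_scores_zero(self):
        assert compute_bsi(0.0, ZEROS) == 0.0

    def test_hand_worked_value(self):
        # half dead, one of seven categories fully altered:
        # 0.5 * (100/700) + 0.5 = 4/7
        assert compute_bsi(50.0, (100, 0, 0, 0, 0, 0, 0)) == pytest.approx(4 / 7)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="bc"):
            compute_bsi(10.0, (1, 2, 3), bc=7)
        with pytest.raises(ValueError):
            BsiInputs(dorg_pct=10.0, ba_pct=(1.0, 2.0), bc=7)

    @pytest.mark.parametrize("dorg,ba", [(-1, ZEROS), (101, ZEROS), (0, (0,) * 6 + (101,))])
    def test_out_of_range_rejected(self, dorg, ba):
        with pytest.raises(ValueError):
            compute_bsi(dorg, ba)

    @given(
        dorg=st.floats(0, 100),
        ba=st.lists(st.floats(0, 100), min_size=7, max_size=7),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_mortality_floor(self, dorg, ba):
        v = compute_bsi(dorg, tuple(ba))
        assert 0.0 <= v <= 1.0
        assert v >= dorg / 100 - 1e-12

    @given(
        d1=st.floats(0, 100),
        d2=st.floats(0, 100),
        ba=st.lists(st.floats(0, 100), min_size=7, max_size=7),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_mortality(self, d1, d2, ba):
        lo, hi = sorted((d1, d2))
        assert compute_bsi(lo, tuple(ba)) <= compute_bsi(hi, tuple(ba)) + 1e-12


class TestClassifyStress:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.0, StressBand.NO_STRESS),
            (0.19999, StressBand.NO_STRESS),
            (0.2, StressBand.LOW),
            (0.39999, StressBand.LOW),
            (0.4, StressBand.MODERATE),
            (4 / 7, StressBand.MODERATE),
            (0.6, StressBand.HIGH),
            (0.8, StressBand.HIGH),  # extreme band is open at 0.8
            (0.80001, StressBand.EXTREME),
            (1.0, StressBand.EXTREME),
        ],
    )
    def test_band_boundaries(self, value, band):
        assert classify_stress(value) is band

    def test_out_of_range_rejected(self):
        for v in (-0.01, 1.01, float("nan")):
            with pytest.raises(ValueError):
                classify_stress(v)

    def test_bands_partition_unit_interval(self):
        values = np.linspace(0, 1, 10001)
        bands = [classify_stress(float(v)) for v in values]
        assert set(bands) == set(StressBand)
        # piecewise-constant: band changes only at the printed thresholds
        changes = sorted(
            float(values[i]) for i in range(1, len(values)) if bands[i] != bands[i - 1]
        )
        assert len(changes) == 4
        for found, expected in zip(changes, (0.2, 0.4, 0.6, 0.8)):
            assert abs(found - expected) < 2e-4


def _cage(n_dead, counts=None, time_h=96.0):
    return CageObservation(
        treatment_label="t",
        cage_id="c",
        time_h=time_h,
        n_initial=10,
        n_dead_cum=n_dead,
        behaviour_counts=counts or {},
    )


class TestBsiFromCage:
    def test_all_dead_extreme(self):
        score = bsi_from_cage(_cage(10))
        assert score.value == 1.0 and score.band is StressBand.EXTREME

    def test_untouched_cage(self):
        score = bsi_from_cage(_cage(0))
        assert score.value == 0.0 and score.band is StressBand.NO_STRESS

    def test_half_dead_all_survivors_paralysed(self):
        score = bsi_from_cage(_cage(5, {"paralysis": 5}))
        assert score.value == pytest.approx(4 / 7)
        assert score.band is StressBand.MODERATE


class TestTrajectory:
    def test_mean_and_se_across_cages(self):
        # cages engineered to per-cage BSI 0.2, 0.3, 0.4 (k categories at 70%
        # of survivors give BSI = 0.1 k with no deaths)
        cats = list(BEHAVIOUR_CATEGORIES)
        behaviours = {
            "t": {
                cats[0]: [[0, 7], [0, 7], [0, 7]],
                cats[1]: [[0, 7], [0, 7], [0, 7]],
                cats[2]: [[0, 0], [0, 7], [0, 7]],
                cats[3]: [[0, 0], [0, 0], [0, 7]],
            }
        }
        b = make_bioassay(
            {"t": [[0, 0], [0, 0], [0, 0]]}, behaviours=behaviours, times=(0.0, 96.0)
        )
        traj = bsi_trajectory(b, "t")
        row = traj[traj.time_h == 96.0].iloc[0]
        assert row.mean_bsi == pytest.approx(0.3)
        assert row.se == pytest.approx(np.std([0.2, 0.3, 0.4], ddof=1) / math.sqrt(3))
        assert row.se == pytest.approx(0.0577, abs=5e-4)
        assert row.band == "low"

    def test_all_dead_everywhere(self):
        b = make_bioassay({"t": [[0, 10, 10], [0, 10, 10]]}, times=(0.0, 24.0, 96.0))
        traj = bsi_trajectory(b, "t")
        assert (traj[traj.time_h > 0].mean_bsi == 1.0).all()
        assert (traj[traj.time_h > 0].se == 0.0).all()

    def test_single_cage_se_zero(self):
        b = make_bioassay({"t": [[0, 2]]}, times=(0.0, 96.0))
        traj = bsi_trajectory(b, "t")
        assert (traj.se == 0.0).all()

    def test_unknown_treatment(self):
        b = make_bioassay({"t": [[0, 0]]}, times=(0.0, 96.0))
        with pytest.raises(KeyError):
            bsi_trajectory(b, "zzz")


class TestPermutationContrast:
    def test_identical_groups_give_p_one(self):
        b = make_bioassay(
            {"a": [[0, 0], [0, 0], [0, 0]], "b": [[0, 0], [0, 0], [0, 0]]},
            times=(0.0, 96.0),
        )
        assert permutation_contrast(b, "a", "b", 96.0, n_perm=999, seed=1) == 1.0

    def test_fully_separated_groups_exact_enumeration(self):
        # cage BSI 0 vs 1: of the C(6,3)=20 label assignments exactly the two
        # perfect separations are as extreme, so p = 2/20
        b = make_bioassay(
            {"a": [[0, 0], [0, 0], [0, 0]], "b": [[0, 10], [0, 10], [0, 10]]},
            times=(0.0, 96.0),
        )
        assert permutation_contrast(b, "a", "b", 96.0, n_perm=999, seed=1) == pytest.approx(0.1)

    def test_monte_carlo_path_deterministic_and_bounded(self):
        deaths = {
            "a": [[0, d] for d in (0, 1, 2, 3, 4)],
            "b": [[0, d] for d in (5, 6, 7, 8, 9)],
        }
        b = make_bioassay(deaths, times=(0.0, 96.0))
        p1 = permutation_contrast(b, "a", "b", 96.0, n_perm=99, seed=7)
        p2 = permutation_contrast(b, "a", "b", 96.0, n_perm=99, seed=7)
        assert p1 == p2
        assert p1 >= 1 / 100

    def test_insufficient_replication_rejected(self):
        b = make_bioassay({"a": [[0, 0]], "b": [[0, 1], [0, 2]]}, times=(0.0, 96.0))
        with pytest.raises(ValueError, match="cages"):
            permutation_contrast(b, "a", "b", 96.0)
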