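"""Measurement pipeline: classification, velocity, asymmetry, IOD, Mann-Whitney."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from fiberdyn.combing import Fiber, fragment_into_fibers
from fiberdyn.distributions import DistributionSpec, SpecError
from fiberdyn.fiberanalysis import (
    AnalysisParams,
    analyze_scenario,
    asymmetry_score,
    classify_asymmetric,
    classify_structures,
    estimate_fork_velocity,
    interorigin_distances,
    mann_whitney,
)
from fiberdyn.repsim import CLDU, IDU, UNLABELED, Origin, Segment, simulate_molecules, simulate_replication

PARAMS = AnalysisParams()


def fiber_from_pattern(*parts, pad=50.0):
    """Build a fiber from (label, length) parts with unlabeled padding."""
    segs = [(UNLABELED, pad), *parts, (UNLABELED, pad)]
    out, pos = [], 0.0
    for label, length in segs:
        out.append(Segment(label, pos, pos + length))
        pos += length
    return Fiber("pat", pos, out)


class TestClassification:
    def test_pulse1_origin_with_flanks(self):
        f = fiber_from_pattern((CLDU, 40.0), (IDU, 80.0), (CLDU, 40.0))
        structs = classify_structures(f, PARAMS)
        origins = [s for s in structs if s.kind == "origin_replicon"]
        assert len(origins) == 1
        o = origins[0]
        assert o.left_cldu == 40.0 and o.right_cldu == 40.0
        assert o.center_position == pytest.approx(50.0 + 40.0 + 40.0)
        assert o.asymmetry_eligible

    def test_gap_centred_origin(self):
        f = fiber_from_pattern(
            (CLDU, 40.0), (IDU, 36.0), (UNLABELED, 20.0), (IDU, 36.0), (CLDU, 40.0)
        )
        structs = classify_structures(f, PARAMS)
        origins = [s for s in structs if s.kind == "origin_replicon"]
        assert len(origins) == 1
        assert origins[0].center_position == pytest.approx(50 + 40 + 36 + 10)
        # the two arms are themselves ongoing forks
        forks = [s for s in structs if s.kind == "ongoing_fork"]
        assert len(forks) == 2

    def test_ongoing_fork(self):
        f = fiber_from_pattern((IDU, 36.0), (CLDU, 39.0))
        structs = classify_structures(f, PARAMS)
        assert [s.kind for s in structs] == ["ongoing_fork"]
        assert structs[0].idu_length == 36.0 and structs[0].cldu_length == 39.0

    def test_isolated_tracks(self):
        f = fiber_from_pattern((CLDU, 25.0))
        assert [s.kind for s in classify_structures(f, PARAMS)] == ["second_pulse_only"]
        f = fiber_from_pattern((IDU, 25.0))
        assert [s.kind for s in classify_structures(f, PARAMS)] == ["first_pulse_only"]

    def test_termination_block(self):
        f = fiber_from_pattern((IDU, 30.0), (CLDU, 50.0), (IDU, 30.0))
        kinds = sorted(s.kind for s in classify_structures(f, PARAMS))
        assert kinds == ["termination"]

    def test_merged_cldu_flank_is_not_measurable(self):
        # two origins whose converging forks met during pulse 2: the shared
        # CldU is a termination and neither inner flank is usable
        f = fiber_from_pattern(
            (CLDU, 40.0), (IDU, 36.0), (UNLABELED, 10.0), (IDU, 36.0),
            (CLDU, 70.0),
            (IDU, 36.0), (UNLABELED, 10.0), (IDU, 36.0), (CLDU, 40.0),
        )
        structs = classify_structures(f, PARAMS)
        origins = [s for s in structs if s.kind == "origin_replicon"]
        assert len(origins) == 2
        for o in origins:
            assert not o.asymmetry_eligible
        assert sum(s.kind == "termination" for s in structs) == 1
        # outer arms remain valid forks; inner merged arms do not
        assert sum(s.kind == "ongoing_fork" for s in structs) == 2

    def test_pulse1_merged_pair_keeps_both_centers(self):
        # converging forks met during pulse 1: the middle IdU is a junction,
        # the two initiation gaps are still origins
        f = fiber_from_pattern(
            (CLDU, 40.0), (IDU, 36.0), (UNLABELED, 10.0), (IDU, 80.0),
            (UNLABELED, 10.0), (IDU, 36.0), (CLDU, 40.0),
        )
        structs = classify_structures(f, PARAMS)
        origins = [s for s in structs if s.kind == "origin_replicon"]
        centers = sorted(o.center_position for o in origins)
        assert len(origins) == 2
        assert centers[1] - centers[0] == pytest.approx(10 + 80)
        assert sum(s.kind == "termination" for s in structs) == 1

    def test_structures_touching_fiber_ends_are_censored(self):
        segs = [Segment(IDU, 0.0, 30.0), Segment(CLDU, 30.0, 60.0), Segment(UNLABELED, 60.0, 100.0)]
        f = Fiber("edge", 100.0, segs, left_censored=True)
        structs = classify_structures(f, PARAMS)
        assert all(s.censored for s in structs if s.kind == "ongoing_fork")


class TestVelocity:
    def test_arithmetic_matches_hand_value(self):
        s = classify_structures(fiber_from_pattern((IDU, 35.8), (CLDU, 35.8)), PARAMS)[0]
        assert estimate_fork_velocity(s, PARAMS) == pytest.approx(1.79)

    def test_total_vs_second_pulse_mode(self):
        s = classify_structures(fiber_from_pattern((IDU, 40.0), (CLDU, 40.0)), PARAMS)[0]
        assert estimate_fork_velocity(s, PARAMS) == pytest.approx(2.0)
        p2 = AnalysisParams(velocity_mode="second_pulse_only")
        assert estimate_fork_velocity(s, p2) == pytest.approx(2.0)

    def test_ineligible_structures_excluded(self):
        structs = classify_structures(fiber_from_pattern((IDU, 25.0)), PARAMS)
        assert estimate_fork_velocity(structs[0], PARAMS) is None

    def test_exact_on_noiseless_simulated_forks(self, make_scenario):
        sc = make_scenario(
            region_length=20000.0,
            origin_spacing=DistributionSpec("gamma", mean=300.0, shape=4.0),
            firing_time=DistributionSpec("uniform", low=-6.0, high=-3.0),
            fork_velocity=DistributionSpec("fixed", mean=1.79),
        )
        rng = np.random.default_rng(0)
        mols = simulate_molecules(sc, rng, 2)
        velocities = []
        for i, mol in enumerate(mols):
            for f in fragment_into_fibers(mol, sc, rng, molecule_index=i, fiber_length_mean=1e12):
                for s in classify_structures(f, PARAMS):
                    v = estimate_fork_velocity(s, PARAMS)
                    if v is not None:
                        velocities.append(v)
        assert len(velocities) > 50
        np.testing.assert_allclose(velocities, 1.79, rtol=1e-12)

    def test_measured_velocities_are_true_fork_velocities(self, make_scenario):
        # censored/merged structures never contribute: every reported velocity
        # must exactly equal the velocity of a surviving ground-truth fork
        sc = make_scenario(
            region_length=20000.0,
            origin_spacing=DistributionSpec("gamma", mean=250.0, shape=4.0),
            firing_time=DistributionSpec("uniform", low=-6.0, high=-3.0),
            fork_velocity=DistributionSpec("gamma", mean=1.8, cv=0.1),
            sister_noise_sd=0.03,
            fiber_length=DistributionSpec("lognormal", mean=500.0, sigma_log=0.5),
        )
        rng = np.random.default_rng(5)
        from collections import Counter

        mols = simulate_molecules(sc, rng, 3)
        surviving = Counter()
        measured = []
        for i, mol in enumerate(mols):
            for fk in mol.ground_truth.forks:
                if fk.termination_time is None and not fk.stalled:
                    surviving[round(fk.velocity, 9)] += 1
            for f in fragment_into_fibers(mol, sc, rng, molecule_index=i):
                for s in classify_structures(f, PARAMS):
                    v = estimate_fork_velocity(s, PARAMS)
                    if v is not None:
                        measured.append(v)
        assert len(measured) > 100
        for v in measured:
            key = round(v, 9)
            assert surviving.get(key, 0) > 0
            surviving[key] -= 1


class TestAsymmetry:
    @pytest.mark.parametrize(
        "left,right,score,asym",
        [(10.0, 10.0, 0.0, False), (10.0, 6.0, 0.4, True), (10.0, 8.0, 0.2, False)],
    )
    def test_score_and_threshold(self, left, right, score, asym):
        s = asymmetry_score(left, right)
        assert s == pytest.approx(score)
        assert classify_asymmetric(s, PARAMS) is asym

    def test_score_is_symmetric_and_bounded(self):
        for l, r in [(3.0, 7.0), (120.0, 10.0), (1.0, 1.0)]:
            assert asymmetry_score(l, r) == asymmetry_score(r, l)
            assert 0.0 <= asymmetry_score(l, r) < 1.0

    def test_alternative_rules(self):
        assert asymmetry_score(10.0, 6.0, "relative_min") == pytest.approx(4 / 6)
        assert asymmetry_score(10.0, 6.0, "relative_mean") == pytest.approx(0.5)

    def test_zero_flank_rejected(self):
        with pytest.raises(SpecError):
            asymmetry_score(0.0, 5.0)

    def test_fraction_vanishes_without_stalling_and_noise(self, make_scenario):
        sc = make_scenario(
            region_length=20000.0,
            origin_spacing=DistributionSpec("gamma", mean=300.0, shape=4.0),
            firing_time=DistributionSpec("uniform", low=-6.0, high=-3.0),
            fork_velocity=DistributionSpec("gamma", mean=1.8, cv=0.1),
            sister_noise_sd=0.0,
            stall_rate=0.0,
        )
        rng = np.random.default_rng(0)
        mols = simulate_molecules(sc, rng, 2)
        fibers = []
        for i, mol in enumerate(mols):
            fibers.extend(fragment_into_fibers(mol, sc, rng, molecule_index=i, fiber_length_mean=3000.0))
        rep = analyze_scenario(fibers, PARAMS)
        assert rep.n_replicons > 50
        assert rep.asymmetric_fraction == 0.0

    def test_fraction_increases_with_stall_rate(self, make_scenario):
        fracs = []
        for stall in (0.0, 0.002, 0.01):
            sc = make_scenario(
                region_length=30000.0,
                origin_spacing=DistributionSpec("gamma", mean=300.0, shape=4.0),
                firing_time=DistributionSpec("uniform", low=-6.0, high=-3.0),
                fork_velocity=DistributionSpec("gamma", mean=1.8, cv=0.1),
                sister_noise_sd=0.03,
                stall_rate=stall,
            )
            rng = np.random.default_rng(11)
            mols = simulate_molecules(sc, rng, 6)
            fibers = []
            for i, mol in enumerate(mols):
                fibers.extend(
                    fragment_into_fibers(mol, sc, rng, molecule_index=i, fiber_length_mean=3000.0)
                )
            rep = analyze_scenario(fibers, PARAMS)
            assert rep.n_replicons >= 200
            fracs.append(rep.asymmetric_fraction)
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] > fracs[0]


class TestInterorigin:
    def _origin(self, center):
        return [
            (CLDU, 40.0), (IDU, 30.0), (UNLABELED, 10.0), (IDU, 30.0), (CLDU, 40.0),
        ]

    def _fiber_with_centers(self, centers, length=1000.0):
        parts = []
        pos = 0.0
        segs = []
        for c in centers:
            start = c - 75.0  # origin block spans 150 kb centred on c
            segs.append(Segment(UNLABELED, pos, start))
            for label, ln in self._origin(c):
                segs.append(Segment(label, start, start + ln))
                start += ln
            pos = start
        segs.append(Segment(UNLABELED, pos, length))
        segs = [s for s in segs if s.end > s.start]
        return Fiber("iod", length, segs)

    def test_two_origins(self):
        f = self._fiber_with_centers([100.0, 275.0])
        d = interorigin_distances([f], PARAMS)
        np.testing.assert_allclose(d, [175.0])

    def test_single_origin_warns_empty(self):
        f = self._fiber_with_centers([300.0])
        with pytest.warns(UserWarning):
            d = interorigin_distances([f], PARAMS)
        assert d.size == 0

    def test_three_origins_adjacent_differences(self):
        f = self._fiber_with_centers([100.0, 300.0, 600.0], length=1500.0)
        np.testing.assert_allclose(interorigin_distances([f], PARAMS), [200.0, 300.0])

    def test_converges_to_configured_spacing_with_longer_fibers(self, make_scenario):
        sc = make_scenario(
            region_length=40000.0,
            origin_spacing=DistributionSpec("gamma", mean=175.0, shape=4.0),
            firing_time=DistributionSpec("uniform", low=-6.0, high=-3.0),
            fork_velocity=DistributionSpec("gamma", mean=1.79, cv=0.1),
            sister_noise_sd=0.03,
        )
        errors = []
        for flm in (600.0, 1500.0, 4000.0):
            rng = np.random.default_rng(21)
            mols = simulate_molecules(sc, rng, 3)
            fibers = []
            for i, mol in enumerate(mols):
                fibers.extend(
                    fragment_into_fibers(mol, sc, rng, molecule_index=i, fiber_length_mean=flm)
                )
            rep = analyze_scenario(fibers, PARAMS)
            errors.append(abs(rep.iod_mean - 175.0))
        assert errors[-1] < 10.0
        assert errors[-1] <= errors[0] + 3.0  # monotone up to MC noise


def exhaustive_mw_p(a, b):
    """Independent oracle: full enumeration of label assignments (midranks)."""
    a, b = list(a), list(b)
    n1 = len(a)
    pooled = np.asarray(a + b, dtype=float)
    ranks = stats.rankdata(pooled)
    m = n1 * len(b) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - m) >= abs(u_obs - m) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.U == 0.0
        assert r.p == pytest.approx(0.1)
        assert r.method == "exact"

    def test_identical_samples(self):
        r = mann_whitney([2.0, 2.0, 3.0], [2.0, 2.0, 3.0])
        assert r.p == 1.0
        assert r.direction == "none"

    def test_large_shift_tiny_p(self):
        a = np.random.default_rng(1).normal(0.0, 1.0, 500)
        r = mann_whitney(a, a + 3.0)
        assert r.p < 1e-10
        assert r.method == "normal"
        assert r.direction == "b_greater"

    def test_empty_sample_rejected(self):
        with pytest.raises(SpecError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 7) for n2 in range(n1, 7)])
    def test_matches_enumeration_oracle_small_n(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(4):
            # mix of continuous values and heavy ties
            a = rng.choice([0.0, 1.0, 2.0, 2.5, 7.0], n1).tolist()
            b = rng.choice([0.0, 1.0, 2.0, 3.5, 7.0], n2).tolist()
            r = mann_whitney(a, b)
            assert r.method == "exact"
            assert r.p == pytest.approx(exhaustive_mw_p(a, b))
            assert 0.0 <= r.U <= n1 * n2

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 6)
            r = mann_whitney(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert r.U == pytest.approx(ref.statistic)
            assert r.p == pytest.approx(ref.pvalue)

    def test_u_plus_mirror_u_is_n1n2(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 1, 9)
        assert mann_whitney(a, b).U + mann_whitney(b, a).U == pytest.approx(8 * 9)


class TestScenarioReport:
    def test_insufficient_data_flag(self):
        f = fiber_from_pattern((IDU, 36.0), (CLDU, 39.0))
        with pytest.warns(UserWarning):
            rep = analyze_scenario([f], PARAMS)
        assert rep.velocity.n == 1
        assert rep.insufficient_data
        assert math.isnan(rep.iod_mean)

    def test_no_forks_at_all(self):
        f = fiber_from_pattern((CLDU, 25.0))
        with pytest.warns(UserWarning):
            rep = analyze_scenario([f], PARAMS)
        assert rep.velocity.n == 0
        assert math.isnan(rep.velocity.mean)

    def test_replicate_grouping_statistics(self, make_scenario):
        sc = make_scenario(
            region_length=20000.0,
            origin_spacing=DistributionSpec("gamma", mean=300.0, shape=4.0),
            firing_time=DistributionSpec("uniform", low=-6.0, high=-3.0),
            fork_velocity=DistributionSpec("gamma", mean=1.8, cv=0.1),
            sister_noise_sd=0.03,
            stall_rate=0.005,
        )
        rng = np.random.default_rng(4)
        mols = simulate_molecules(sc, rng, 3)
        fibers = []
        for i, mol in enumerate(mols):
            fibers.extend(fragment_into_fibers(mol, sc, rng, molecule_index=i, fiber_length_mean=2500.0))
        rep = analyze_scenario(fibers, PARAMS)
        assert len(rep.asymmetric_fraction_by_replicate) == 3
        assert rep.asymmetric_fraction_mean == pytest.approx(
            np.mean(rep.asymmetric_fraction_by_replicate)
        )
        assert rep.asymmetric_fraction_sd >= 0.0
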