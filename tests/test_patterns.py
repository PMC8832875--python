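"""Pattern analysis: regimes, power laws, factor fits, alpha constancy."""

import math

import numpy as np
import pytest

import levelflux as lf
from levelflux.diagram import Species, SystemSpec, SystemState, Transformation
from levelflux.dynamics import Trajectory
from levelflux.patterns import (
    InsufficientDataError,
    PathUndefinedError,
    UndefinedSlopeError,
    entropy_vs_potential,
)


def synthetic_trajectory(t, columns, species_ids, n_transformations=2):
    states = np.column_stack(columns)
    n = len(t)
    return Trajectory(
        times=np.asarray(t, float),
        states=states,
        entropy_series=np.full(n, np.nan),
        power_series=np.full(n, np.nan),
        affinity_series=np.zeros((n, n_transformations)),
        species_ids=list(species_ids),
    )


@pytest.fixture(scope="module")
def three_species_spec():
    return lf.make_chain(M=3)


def three_phase_curve(dt=0.02):
    """Exponential (rate 2) to t=1, cubic power-law coupling to t=2, then
    exponential saturation (rate 3); N1 = N3**(1/3) throughout."""
    t = np.arange(0.0, 3.0 + dt / 2, dt)
    e2 = math.exp(2.0)
    N3 = np.where(
        t <= 1.0,
        np.exp(2 * t),
        np.where(t <= 2.0, e2 * t**3, 12 * e2 - 4 * e2 * np.exp(-3 * (t - 2.0))),
    )
    return t, N3 ** (1 / 3), N3 ** (2 / 3), N3


class TestSegmentRegimes:
    def test_three_phase_boundaries_within_one_sample(self, three_species_spec):
        dt = 0.02
        t, N1, N2, N3 = three_phase_curve(dt)
        traj = synthetic_trajectory(t, [N1, N2, N3], three_species_spec.species_ids)
        seg = lf.segment_regimes(traj, three_species_spec, "X3")
        assert seg.onset is not None and seg.body is not None and seg.flattening is not None
        assert abs(seg.onset.t_end - 1.0) <= dt + 1e-12
        assert abs(seg.flattening.t_start - 2.0) <= dt + 1e-12
        assert seg.onset.rate == pytest.approx(2.0, rel=1e-6)
        assert seg.body.rate == pytest.approx(3.0, rel=1e-9)
        assert seg.flattening.rate == pytest.approx(3.0, rel=0.02)

    def test_pure_exponential_is_all_onset(self, three_species_spec):
        t = np.linspace(0.0, 2.0, 80)
        N3 = np.exp(1.7 * t)
        traj = synthetic_trajectory(
            t, [N3 ** (1 / 3), N3 ** (2 / 3), N3], three_species_spec.species_ids
        )
        seg = lf.segment_regimes(traj, three_species_spec, "X3")
        assert seg.onset is not None
        assert seg.onset.rate == pytest.approx(1.7, rel=0.01)
        assert any("onset" in f for f in seg.flags)  # never leaves onset
        assert seg.body is None and seg.flattening is None

    def test_logistic_has_onset_and_flattening(self, three_species_spec):
        t = np.linspace(0.0, 20.0, 400)
        N3 = 50.0 / (1.0 + np.exp(-0.8 * (t - 10.0)))
        traj = synthetic_trajectory(
            t, [N3 ** (1 / 3), N3 ** (2 / 3), N3], three_species_spec.species_ids
        )
        seg = lf.segment_regimes(traj, three_species_spec, "X3")
        assert seg.onset is not None and seg.onset.goodness >= 0.99
        assert seg.flattening is not None and seg.flattening.goodness >= 0.99
        assert seg.onset.rate == pytest.approx(0.8, rel=0.05)

    def test_non_monotone_series_flagged_undefined(self, three_species_spec):
        t = np.linspace(0.0, 10.0, 200)
        N3 = 5.0 + 2.0 * np.sin(t)
        traj = synthetic_trajectory(
            t, [N3 ** (1 / 3), N3 ** (2 / 3), N3], three_species_spec.species_ids
        )
        seg = lf.segment_regimes(traj, three_species_spec, "X3")
        assert seg.onset is None
        assert any("segmentation-undefined" in f for f in seg.flags)

    def test_chain_growth_recovers_composition_slopes(self, chain_sourced_spec, chain_growth_traj):
        for sid, c in [("X2", 2.0), ("X3", 3.0)]:
            seg = lf.segment_regimes(chain_growth_traj, chain_sourced_spec, sid)
            assert seg.onset is not None and seg.onset.goodness >= 0.98
            assert seg.body is not None
            assert seg.body.rate == pytest.approx(c, rel=0.05)

    def test_time_rescaling_leaves_loglog_slopes_unchanged(self, three_species_spec):
        t, N1, N2, N3 = three_phase_curve()
        traj = synthetic_trajectory(t, [N1, N2, N3], three_species_spec.species_ids)
        scaled = synthetic_trajectory(10.0 * t, [N1, N2, N3], three_species_spec.species_ids)
        s1 = lf.segment_regimes(traj, three_species_spec, "X3")
        s2 = lf.segment_regimes(scaled, three_species_spec, "X3")
        assert s2.body.rate == pytest.approx(s1.body.rate, rel=1e-9)


class TestPowerLawSlope:
    @pytest.mark.parametrize("a", [1.0, 0.1, 17.3])
    def test_exact_power_relation_recovered_to_machine_precision(self, three_species_spec, a):
        t = np.linspace(0.0, 1.0, 60)
        N1 = np.exp(np.linspace(0.0, 2.0, 60))
        traj = synthetic_trajectory(
            t, [N1, N1**2, a * N1**3], three_species_spec.species_ids
        )
        slope = lf.power_law_slope(traj, three_species_spec, "X3", (0.0, 1.0))
        assert abs(slope - 3.0) <= 1e-10

    def test_constant_elemental_population_is_degenerate(self, three_species_spec):
        t = np.linspace(0.0, 1.0, 30)
        traj = synthetic_trajectory(
            t, [np.full(30, 2.0), np.linspace(1, 2, 30), np.linspace(1, 4, 30)],
            three_species_spec.species_ids,
        )
        with pytest.raises(UndefinedSlopeError):
            lf.power_law_slope(traj, three_species_spec, "X3", (0.0, 1.0))


class TestFactorDistribution:
    def test_exact_geometric_cascade_fits_perfectly(self):
        spec = lf.make_chain(M=5)
        phi1 = 1.7
        # populations chosen so phi_j = phi_1**c_j exactly (G = 0)
        state = SystemState(np.array([phi1**j for j in range(1, 6)]))
        fit = lf.fit_factor_distribution(state, spec)
        assert fit.goodness == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(math.log(phi1), rel=1e-12)
        assert fit.lognormal

    def test_near_balance_chain_state(self, chain_spec, chain_balanced_traj):
        fit = lf.fit_factor_distribution(chain_balanced_traj.final_state(), chain_spec)
        assert fit.goodness >= 0.95
        assert fit.lognormal

    def test_two_positive_species_insufficient(self):
        spec = lf.make_chain(M=5)
        state = SystemState(np.array([1.0, 2.0, 0.0, 0.0, 0.0]))
        with pytest.raises(InsufficientDataError):
            lf.fit_factor_distribution(state, spec)


class TestAlphaFactor:
    def test_unity_at_balance(self, chain_spec, chain_balanced_traj):
        t_end = chain_balanced_traj.times[-1]
        rep = lf.alpha_factor(
            chain_balanced_traj, chain_spec, "X3", (0.9 * t_end, t_end)
        )
        np.testing.assert_allclose(rep.alpha, 1.0, atol=1e-6)
        assert rep.drift <= 1e-6

    def test_approximately_constant_through_body(self, chain_sourced_spec, chain_growth_traj):
        seg = lf.segment_regimes(chain_growth_traj, chain_sourced_spec, "X3")
        rep = lf.alpha_factor(chain_growth_traj, chain_sourced_spec, "X3", seg.body.window)
        assert rep.drift <= 0.2

    def test_unreachable_species_raises(self):
        spec = SystemSpec(
            species=(
                Species("A", 0.0, c=1, N0=1.0),
                Species("B", 0.0, c=1, N0=1.0),
                Species("Z", 0.0, c=1, N0=1.0),
            ),
            transformations=(
                Transformation(substrates={"A": 1}, products={"B": 1}),
            ),
        )
        traj = synthetic_trajectory(
            np.linspace(0, 1, 10),
            [np.ones(10)] * 3,
            spec.species_ids,
            n_transformations=1,
        )
        with pytest.raises(PathUndefinedError):
            lf.alpha_factor(traj, spec, "Z", (0.0, 1.0))


class TestEntropyVsPotential:
    def test_constant_trajectory_flagged(self, three_species_spec):
        t = np.linspace(0, 1, 20)
        traj = synthetic_trajectory(
            t, [np.full(20, 2.0)] * 3, three_species_spec.species_ids
        )
        curve = entropy_vs_potential(traj, three_species_spec)
        assert curve.slope is None
        assert any("undefined" in f for f in curve.flags)

    def test_two_point_curve_low_confidence(self, three_species_spec):
        traj = synthetic_trajectory(
            [0.0, 1.0],
            [np.array([3.0, 4.0]), np.array([3.0, 5.0]), np.array([3.0, 6.0])],
            three_species_spec.species_ids,
        )
        curve = entropy_vs_potential(traj, three_species_spec)
        assert curve.slope is not None
        assert any("low-confidence" in f for f in curve.flags)

    def test_chain_relaxation_has_finite_slope(self, chain_sourced_spec, chain_growth_traj):
        curve = entropy_vs_potential(chain_growth_traj, chain_sourced_spec)
        assert curve.slope is not None and np.isfinite(curve.slope)
        assert curve.goodness is not None
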