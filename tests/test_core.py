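"""Unit and property tests for the leaky-integrator core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgloops.core import (
    Network,
    NoiseSource,
    Projection,
    UnitGroup,
    da_gain,
    transfer,
)


class TestTransfer:
    @pytest.mark.parametrize(
        "u, alpha, theta, expected",
        [
            (0.5, 1.0, 0.6, 0.0),          # below threshold clips to zero
            (0.6, 1.0, 0.6, 0.0),          # boundary of the positive part
            (0.6, 7.3, 0.6, 0.0),
            (1.1, 1.0, 0.6, np.tanh(0.5)),  # direct evaluation
        ],
    )
    def test_values(self, u, alpha, theta, expected):
        assert transfer(u, alpha, theta) == pytest.approx(expected, abs=1e-12)

    @given(
        u=st.floats(-100, 100),
        alpha=st.floats(0.01, 50),
        theta=st.floats(-5, 5),
    )
    def test_bounded_and_thresholded(self, u, alpha, theta):
        y = transfer(u, alpha, theta)
        assert 0.0 <= y < 1.0
        if u <= theta:
            assert y == 0.0

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            transfer(0.5, 0.0, 0.0)


class TestDaGain:
    @pytest.mark.parametrize(
        "eps, lam, d, expected",
        [
            (1.0, 0.0, 3.7, 1.0),    # unmodulated units ignore DA entirely
            (0.5, 2.5, 0.0, 0.5),    # zero DA leaves epsilon
            (0.5, 1.5, 0.4, 1.1),
        ],
    )
    def test_values(self, eps, lam, d, expected):
        assert da_gain(eps, lam, d) == pytest.approx(expected)


def single_unit(tau=0.1, basal=0.0, eps=1.0, lam=0.0, alpha=1.0):
    return Network([UnitGroup("g", 1, tau=tau, basal=basal, epsilon=eps,
                              lam=lam, alpha=alpha)])


class TestStep:
    def test_leak_fixed_point(self):
        """With zero input, u converges monotonically to the basal level."""
        net = single_unit(basal=0.3)
        gaps = []
        for _ in range(2000):
            net.step(0.01)
            gaps.append(abs(net.state.u[0] - 0.3))
        assert net.state.u[0] == pytest.approx(0.3, abs=1e-4)
        assert all(b <= a + 1e-15 for a, b in zip(gaps, gaps[1:]))

    def test_exponential_decay(self):
        """Zero weights, zero basal: u decays with the group time constant."""
        net = single_unit(tau=0.25)
        net.state.u[0] = 1.0
        for _ in range(100):
            net.step(0.001)
        assert net.state.u[0] == pytest.approx(np.exp(-0.1 / 0.25), rel=1e-3)

    def test_chain_matches_fine_step_oracle(self):
        """A 3-unit chain at dt=0.01 matches 100x-finer Euler to 1e-3."""
        def build():
            groups = [
                UnitGroup("a", 1, tau=0.2, basal=0.5),
                UnitGroup("b", 1, tau=0.15, alpha=1.0),
                UnitGroup("c", 1, tau=0.1, alpha=1.0),
            ]
            projections = [
                Projection("a", "b", "parallel", "excitatory", 0.5),
                Projection("b", "c", "parallel", "excitatory", 0.6),
            ]
            return Network(groups, projections)

        coarse, fine = build(), build()
        for _ in range(100):
            coarse.step(0.01)
        for _ in range(10000):
            fine.step(0.0001)
        np.testing.assert_allclose(coarse.state.u, fine.state.u, atol=1e-3)

    def test_rejects_unstable_dt(self):
        net = single_unit(tau=0.1)
        with pytest.raises(ValueError, match="unstable"):
            net.step(0.1)
        with pytest.raises(ValueError):
            net.step(-0.01)

    def test_divergence_raises(self):
        net = Network(
            [UnitGroup("g", 1, tau=1.0)],
            [Projection("g", "g", "parallel", "excitatory", 1e9)],
        )
        net.state.u[0] = 1.0
        net.state.y[0] = 0.9
        with pytest.raises(FloatingPointError):
            for _ in range(100):
                net.step(0.01)


class TestRun:
    def test_zero_duration_returns_initial_state_only(self):
        ts = single_unit().run(0.0)
        assert len(ts.t) == 1 and ts.t[0] == 0.0

    def test_constant_input_analytic_fixed_point(self):
        """u* = b + (eps + lam*d) * w * I for a single driven unit."""
        eps, lam, d, w, I, b = 0.4, 1.5, 1.2, 0.7, 0.5, 0.2
        drive = Network(
            [UnitGroup("g", 1, tau=0.1, basal=b, epsilon=eps, lam=lam)],
        )
        ts = drive.run(5.0, da=d, inputs={"g": lambda t: np.array([w * I])})
        assert ts.u[-1, 0] == pytest.approx(b + (eps + lam * d) * w * I, rel=1e-4)

    def test_identical_seeds_identical_trajectories(self):
        def noisy():
            return Network(
                [UnitGroup("g", 3, tau=0.1,
                           noise=NoiseSource(strength=10.0, decay=100.0))]
            )

        a = noisy().run(2.0, seed=123)
        b = noisy().run(2.0, seed=123)
        c = noisy().run(2.0, seed=124)
        np.testing.assert_array_equal(a.u, b.u)
        assert not np.array_equal(a.u, c.u)

    def test_da_neutral_groups_ignore_da_schedule(self):
        """With eps=1, lam=0 everywhere, trajectories are bitwise identical
        for any DA schedule under the same seed."""
        def build():
            return Network(
                [UnitGroup("g", 2, tau=0.1,
                           noise=NoiseSource(strength=5.0, decay=50.0))],
                [Projection("g", "g", "lateral_inhibition", "inhibitory", 0.3)],
            )

        lo = build().run(2.0, da=0.0, seed=7)
        hi = build().run(2.0, da=lambda t: 5.0 + np.sin(t), seed=7)
        np.testing.assert_array_equal(lo.u, hi.u)
        np.testing.assert_array_equal(lo.y, hi.y)


class TestProjectionTopologies:
    def test_parallel_requires_equal_channels(self):
        with pytest.raises(ValueError, match="parallel"):
            Network(
                [UnitGroup("a", 2, tau=0.1), UnitGroup("b", 3, tau=0.1)],
                [Projection("a", "b", "parallel")],
            )

    def test_diffuse_sums_all_sources(self):
        p = Projection("a", "b", "diffuse", "excitatory", 0.5)
        np.testing.assert_array_equal(p.matrix(3, 2), 0.5 * np.ones((2, 3)))

    def test_lateral_inhibition_excludes_self(self):
        p = Projection("a", "a", "lateral_inhibition", "inhibitory", 2.0)
        m = p.matrix(3, 3)
        assert np.all(np.diag(m) == 0)
        off = m[~np.eye(3, dtype=bool)]
        assert np.all(off == -2.0)

    def test_inhibitory_sign_flips_weight(self):
        p = Projection("a", "b", "parallel", "inhibitory", 0.7)
        np.testing.assert_array_equal(p.matrix(2, 2), -0.7 * np.eye(2))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_activation_bounds_on_random_noisy_network(seed):
    """0 <= y < 1 at every sample of a randomly wired noisy network."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 4))
    groups = [
        UnitGroup(
            f"g{i}",
            int(rng.integers(1, 4)),
            tau=float(rng.uniform(0.05, 0.5)),
            basal=float(rng.uniform(-0.5, 1.0)),
            alpha=float(rng.uniform(0.5, 3.0)),
            theta=float(rng.uniform(0.0, 0.8)),
            epsilon=float(rng.uniform(0.0, 1.0)),
            lam=float(rng.uniform(0.0, 2.5)),
            noise=NoiseSource(strength=float(rng.uniform(0, 30)),
                              decay=float(rng.uniform(10, 2000))),
        )
        for i in range(n)
    ]
    projections = []
    for _ in range(int(rng.integers(0, 5))):
        a, b = rng.choice(n, 2)
        projections.append(
            Projection(
                f"g{a}", f"g{b}", "diffuse",
                "excitatory" if rng.random() < 0.5 else "inhibitory",
                float(rng.uniform(0.0, 1.5)),
            )
        )
    ts = Network(groups, projections).run(1.0, da=1.3, seed=seed, stride=5)
    assert np.all(ts.y >= 0.0) and np.all(ts.y < 1.0)
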