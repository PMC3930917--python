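"""Leaky-integrator rate networks with multiplicative dopamine gain.

The basic building block is a pool ("group") of channelized leaky-integrator
units.  A unit ``j`` of group ``g`` integrates

    tau_g du_j/dt = -u_j + b_j + (eps_g + lam_g * d) * sum_i w_ji y_i

where ``d`` is the current dopamine level and the gain ``eps + lam*d``
multiplies the *total* summed input of the group.  Activations are read out
through a thresholded saturating transfer

    y_j = [tanh(alpha_g * (u_j - theta_g))]^+

so that 0 <= y_j < 1 always, with y_j = 0 below the group threshold.

Networks are integrated with fixed-step forward Euler; all randomness
(smoothed thalamic noise) is drawn from named, seeded streams so identical
seeds give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "transfer",
    "da_gain",
    "NoiseSource",
    "UnitGroup",
    "Projection",
    "Network",
    "NetworkState",
    "TimeSeries",
]


def transfer(u: np.ndarray | float, alpha: float, theta: float) -> np.ndarray | float:
    """Thresholded saturating transfer: ``[tanh(alpha*(u - theta))]^+``.

    Total on all real inputs; output lies in ``[0, 1)`` and is exactly 0 for
    ``u <= theta``.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    out = np.tanh(alpha * (np.asarray(u, dtype=float) - theta))
    # tanh is strictly below 1 but rounds to 1.0 in floats for large
    # arguments; clip to keep the open upper bound exact
    top = np.nextafter(1.0, 0.0)
    clipped = np.clip(out, 0.0, top)
    return clipped if isinstance(out, np.ndarray) and out.ndim else float(clipped)


def da_gain(epsilon: float, lam: float, d: float) -> float:
    """Multiplicative dopamine gain ``epsilon + lam * d``.

    Units untouched by dopamine use ``epsilon = 1, lam = 0`` so the gain is
    identically 1 at every dopamine level.
    """
    return epsilon + lam * d


@dataclass(frozen=True)
class NoiseSource:
    """Smoothed random drive injected into every unit of a group.

    Each integration step a uniform variate is drawn per unit, centred,
    scaled by ``strength`` and fed to a per-unit first-order smoother with
    time constant ``decay`` seconds.  The smoothed value enters the unit's
    summed input.  The smoother turns the white draws into a slow random
    walk whose excursions occasionally overcome tonic pallidal inhibition
    of the thalamus.
    """

    strength: float
    decay: float

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("noise strength must be >= 0")
        if self.decay <= 0:
            raise ValueError("noise decay must be > 0")


@dataclass(frozen=True)
class UnitGroup:
    """A named pool of channelized leaky-integrator units.

    Parameters
    ----------
    name : str
        Group identifier, unique within a network.
    n_channels : int
        Number of units (one per competing channel).
    tau : float
        Integration time constant in seconds.
    basal : float
        Basal activation ``b`` (same for every unit of the group).
    alpha : float
        Slope of the transfer function.
    theta : float
        Transfer threshold; zero for all sub-cortical groups, positive for
        cortical layers.
    epsilon, lam : float
        Dopamine gain coefficients; groups not modulated by dopamine keep
        ``epsilon = 1, lam = 0``.
    noise : NoiseSource, optional
        Smoothed noise drive (used in the thalamus of the motor and
        attention loops).
    """

    name: str
    n_channels: int
    tau: float
    basal: float = 0.0
    alpha: float = 1.0
    theta: float = 0.0
    epsilon: float = 1.0
    lam: float = 0.0
    noise: Optional[NoiseSource] = None

    def __post_init__(self) -> None:
        if self.n_channels <= 0:
            raise ValueError(f"group {self.name!r}: n_channels must be positive")
        if self.tau <= 0:
            raise ValueError(f"group {self.name!r}: tau must be > 0")
        if self.alpha <= 0:
            raise ValueError(f"group {self.name!r}: alpha must be > 0")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"group {self.name!r}: epsilon must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError(f"group {self.name!r}: lam must be >= 0")


@dataclass(frozen=True)
class Projection:
    """Signed, weighted connection between two groups.

    ``parallel`` topology is channel-to-channel (diagonal), ``diffuse``
    connects every source unit to every target unit with equal weight and
    ``lateral_inhibition`` is within-group all-to-all excluding self,
    always inhibitory.
    """

    source: str
    target: str
    topology: str = "parallel"
    sign: str = "excitatory"
    weight: Union[float, np.ndarray] = 1.0
    plastic: bool = False

    def __post_init__(self) -> None:
        if self.topology not in ("parallel", "diffuse", "lateral_inhibition"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown sign {self.sign!r}")
        if self.topology == "lateral_inhibition":
            if self.source != self.target:
                raise ValueError("lateral_inhibition must be within-group")
            if self.sign != "inhibitory":
                raise ValueError("lateral_inhibition must be inhibitory")

    def matrix(self, n_source: int, n_target: int) -> np.ndarray:
        """Effective signed weight matrix of shape (n_target, n_source)."""
        s = 1.0 if self.sign == "excitatory" else -1.0
        if isinstance(self.weight, np.ndarray):
            w = np.asarray(self.weight, dtype=float)
            if w.shape != (n_target, n_source):
                raise ValueError(
                    f"explicit weight matrix for {self.source}->{self.target} "
                    f"has shape {w.shape}, expected {(n_target, n_source)}"
                )
            return s * w
        if self.topology == "parallel":
            if n_source != n_target:
                raise ValueError(
                    f"parallel projection {self.source}->{self.target} needs "
                    f"equal channel counts ({n_source} != {n_target})"
                )
            return s * self.weight * np.eye(n_target)
        if self.topology == "diffuse":
            return s * self.weight * np.ones((n_target, n_source))
        # lateral inhibition: all-to-all minus self
        return -abs(self.weight) * (np.ones((n_target, n_source)) - np.eye(n_target))


@dataclass
class NetworkState:
    """Instantaneous state of a network: potentials, activations, time, DA."""

    u: np.ndarray
    y: np.ndarray
    t: float = 0.0
    d: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.u.copy(), self.y.copy(), self.t, self.d)


@dataclass
class TimeSeries:
    """Sampled trajectories of a run: t, u, y (units stacked), d."""

    t: np.ndarray
    u: np.ndarray
    y: np.ndarray
    d: np.ndarray
    index: Dict[str, slice]

    def y_of(self, group: str) -> np.ndarray:
        return self.y[:, self.index[group]]

    def u_of(self, group: str) -> np.ndarray:
        return self.u[:, self.index[group]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame with columns t, group, channel, u, y, d."""
        rows = []
        for name, sl in self.index.items():
            n = sl.stop - sl.start
            for c in range(n):
                rows.append(
                    pd.DataFrame(
                        {
                            "t": self.t,
                            "group": name,
                            "channel": c,
                            "u": self.u[:, sl.start + c],
                            "y": self.y[:, sl.start + c],
                            "d": self.d,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


InputFn = Callable[[float], np.ndarray]
DaFn = Union[float, Callable[[float], float]]


class Network:
    """Groups + projections with steppable state and seeded noise streams.

    External input is supplied per step as a mapping ``group -> vector`` (or
    as a callable of time to :meth:`run`) and is added to the group's summed
    input, i.e. inside the dopamine gain of the target group.
    """

    def __init__(
        self,
        groups: Sequence[UnitGroup],
        projections: Sequence[Projection] = (),
        seed: Optional[int] = None,
    ) -> None:
        names = [g.name for g in groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        self.groups: Dict[str, UnitGroup] = {g.name: g for g in groups}
        self.projections: List[Projection] = list(projections)
        self.index: Dict[str, slice] = {}
        off = 0
        for g in groups:
            self.index[g.name] = slice(off, off + g.n_channels)
            off += g.n_channels
        self.n_units = off
        self._assemble()
        # per-unit parameter vectors
        self._tau = np.empty(off)
        self._b = np.empty(off)
        self._eps = np.empty(off)
        self._lam = np.empty(off)
        for g in groups:
            sl = self.index[g.name]
            self._tau[sl] = g.tau
            self._b[sl] = g.basal
            self._eps[sl] = g.epsilon
            self._lam[sl] = g.lam
        self.min_tau = float(self._tau.min())
        self._noise_groups = [g for g in groups if g.noise is not None]
        self.reset(seed)

    # -- wiring -----------------------------------------------------------

    def _assemble(self) -> None:
        W = np.zeros((self.n_units, self.n_units))
        for p in self.projections:
            if p.source not in self.index or p.target not in self.index:
                raise KeyError(f"projection {p.source}->{p.target}: unknown group")
            src, tgt = self.index[p.source], self.index[p.target]
            W[tgt, src.start : src.stop] += p.matrix(
                src.stop - src.start, tgt.stop - tgt.start
            )
        self.W = W

    # -- state ------------------------------------------------------------

    def reset(self, seed: Optional[int] = None) -> NetworkState:
        """Zero the state and re-seed the per-group noise streams."""
        ss = np.random.SeedSequence(0 if seed is None else seed)
        children = ss.spawn(max(len(self._noise_groups), 1))
        self._noise_rng = {
            g.name: np.random.default_rng(children[i])
            for i, g in enumerate(self._noise_groups)
        }
        self._noise_state = {
            g.name: np.zeros(g.n_channels) for g in self._noise_groups
        }
        self.state = NetworkState(
            u=np.zeros(self.n_units), y=np.zeros(self.n_units), t=0.0, d=0.0
        )
        return self.state

    def noise_values(self) -> Dict[str, np.ndarray]:
        """Current smoothed noise per noisy group (copies)."""
        return {k: v.copy() for k, v in self._noise_state.items()}

    # -- integration ------------------------------------------------------

    def step(
        self,
        dt: float,
        d: float = 0.0,
        external: Optional[Mapping[str, np.ndarray]] = None,
    ) -> NetworkState:
        """Advance the state by one forward-Euler step of length ``dt``.

        Raises ``ValueError`` if ``dt`` is not a stable step for the fastest
        group and ``FloatingPointError`` if the state diverges.
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if dt >= self.min_tau:
            raise ValueError(
                f"dt={dt} >= min group tau={self.min_tau}: unstable Euler step"
            )
        st = self.state
        x = self.W @ st.y
        # advance smoothed noise and add it to the summed input
        for g in self._noise_groups:
            ns = self._noise_state[g.name]
            draw = self._noise_rng[g.name].random(g.n_channels) - 0.5
            ns += (g.noise.strength * draw - ns) * (dt / g.noise.decay)
            x[self.index[g.name]] += ns
        if external:
            for name, vec in external.items():
                sl = self.index[name]
                v = np.asarray(vec, dtype=float)
                if v.shape != (sl.stop - sl.start,):
                    raise ValueError(
                        f"external input for {name!r} has shape {v.shape}, "
                        f"expected {(sl.stop - sl.start,)}"
                    )
                x[sl] += v
        gain = self._eps + self._lam * d
        st.u += (dt / self._tau) * (-st.u + self._b + gain * x)
        if not np.all(np.isfinite(st.u)) or np.any(np.abs(st.u) > 1e6):
            raise FloatingPointError("network state diverged (NaN/overflow in u)")
        for name, g in self.groups.items():
            sl = self.index[name]
            st.y[sl] = transfer(st.u[sl], g.alpha, g.theta)
        st.t += dt
        st.d = d
        return st

    def run(
        self,
        duration: float,
        dt: float = 0.01,
        da: DaFn = 0.0,
        inputs: Optional[Mapping[str, InputFn]] = None,
        seed: Optional[int] = None,
        stride: int = 10,
        reset: bool = True,
    ) -> TimeSeries:
        """Integrate for ``duration`` seconds, sampling every ``stride`` steps.

        ``da`` may be a constant or a callable of time; ``inputs`` maps group
        names to callables of time returning per-channel drive vectors.
        Deterministic given ``seed``.
        """
        if reset:
            self.reset(seed)
        n_steps = int(round(duration / dt))
        d_fn = da if callable(da) else (lambda t, _v=float(da): _v)
        ts_t, ts_u, ts_y, ts_d = [], [], [], []

        def sample() -> None:
            ts_t.append(self.state.t)
            ts_u.append(self.state.u.copy())
            ts_y.append(self.state.y.copy())
            ts_d.append(self.state.d)

        self.state.d = d_fn(0.0)
        sample()
        for k in range(n_steps):
            t = k * dt
            ext = None
            if inputs:
                ext = {name: fn(t) for name, fn in inputs.items()}
            self.step(dt, d=d_fn(t), external=ext)
            if (k + 1) % stride == 0:
                sample()
        return TimeSeries(
            t=np.asarray(ts_t),
            u=np.vstack(ts_u) if ts_u else np.empty((0, self.n_units)),
            y=np.vstack(ts_y) if ts_y else np.empty((0, self.n_units)),
            d=np.asarray(ts_d),
            index=dict(self.index),
        )
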