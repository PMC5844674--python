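"""Lumped-parameter ventilation of a symmetric bifurcating airway tree.

A positive-pressure ventilator injects a tidal volume at the trachea
(generation 0). The conducting tree down to generation 7 is modelled as a
cascade of Poiseuille resistances: at each generation the flow splits
evenly over the ``2**gn`` parallel branches, and the laminar pressure drop
``dP = 8 mu L q / (pi r^4)`` accumulates from the distal outlet boundary
upward. The per-generation lumen pressures at peak inspiratory flow are
the loads handed to the tissue-mechanics stage.

The inspiratory waveform is a rising exponential normalised so its time
integral equals the tidal volume; expiration is a passive decaying
exponential that returns exactly the same volume, matched continuously at
the transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: dynamic viscosity of air, kg/(m s)
AIR_VISCOSITY = 1.79e-5


@dataclass(frozen=True)
class AirwayGeneration:
    """Geometry of one generation of the symmetric airway tree."""

    gn: int
    radius: float  # lumen radius, m
    length: float  # segment length, m
    count: int     # number of parallel branches (2**gn for a symmetric tree)

    def __post_init__(self) -> None:
        if self.gn < 0:
            raise ValueError(f"generation number must be >= 0, got {self.gn}")
        if not self.radius > 0:
            raise ValueError(f"generation {self.gn}: radius must be positive, got {self.radius}")
        if not self.length > 0:
            raise ValueError(f"generation {self.gn}: length must be positive, got {self.length}")
        if self.count < 1:
            raise ValueError(f"generation {self.gn}: branch count must be >= 1, got {self.count}")

    @property
    def cross_section(self) -> float:
        """Lumen cross-sectional area S = pi r^2 of a single branch, m^2."""
        return math.pi * self.radius ** 2


@dataclass(frozen=True)
class AirwayTree:
    """Ordered, contiguous generations 0..max_gn plus the air viscosity."""

    generations: tuple[AirwayGeneration, ...]
    air_viscosity: float = AIR_VISCOSITY

    def __post_init__(self) -> None:
        if not self.generations:
            raise ValueError("tree needs at least one generation")
        for i, g in enumerate(self.generations):
            if g.gn != i:
                raise ValueError(f"generations must be contiguous from 0; slot {i} holds gn {g.gn}")
        if self.air_viscosity <= 0:
            raise ValueError("air viscosity must be positive")

    @property
    def max_gn(self) -> int:
        return self.generations[-1].gn

    def __getitem__(self, gn: int) -> AirwayGeneration:
        return self.generations[gn]


@dataclass(frozen=True)
class VentilatorWaveform:
    """Exponential inspiration/expiration inflow of a volume-controlled ventilator.

    Parameters
    ----------
    tidal_volume : float
        Volume delivered per breath, m^3 (default 420 ml).
    t_in, t_ex : float
        Inspiration and expiration times, s (defaults 0.4 and 2.0).
    shape_tau : float or None
        Time constant of the rising inspiratory exponential; defaults to
        ``t_in / 5`` so the flow is within 1 % of its plateau at end
        inspiration.
    """

    tidal_volume: float = 420e-6
    t_in: float = 0.4
    t_ex: float = 2.0
    shape_tau: float | None = None

    def __post_init__(self) -> None:
        if self.tidal_volume < 0:
            raise ValueError("tidal volume must be >= 0")
        if self.t_in <= 0 or self.t_ex <= 0:
            raise ValueError("inspiration and expiration times must be positive")
        if self.shape_tau is None:
            object.__setattr__(self, "shape_tau", self.t_in / 5.0)
        if self.shape_tau <= 0:
            raise ValueError("shape_tau must be positive")

    @property
    def period(self) -> float:
        return self.t_in + self.t_ex

    # -- closed-form waveform coefficients ---------------------------------
    @property
    def _amplitude(self) -> float:
        """A such that integral of A (1 - exp(-t/tau)) over [0, T_in] = V_T."""
        tau = self.shape_tau
        denom = self.t_in - tau * (1.0 - math.exp(-self.t_in / tau))
        return self.tidal_volume / denom

    @property
    def _q_end_insp(self) -> float:
        return self._amplitude * (1.0 - math.exp(-self.t_in / self.shape_tau))

    @property
    def _tau_ex(self) -> float:
        return self.t_ex / 5.0

    @property
    def _exp_coeff(self) -> float:
        """B of Q_ex(s) = (Q_end - B s/tau_ex) exp(-s/tau_ex), fixing expired volume."""
        tau = self._tau_ex
        x = self.t_ex / tau
        i1 = tau * (1.0 - math.exp(-x))                  # int exp(-s/tau)
        i2 = tau * (1.0 - (1.0 + x) * math.exp(-x))      # int (s/tau) exp(-s/tau)
        return (self.tidal_volume + self._q_end_insp * i1) / i2


def inlet_flow(t, w: VentilatorWaveform, periodic: bool = False):
    """Ventilator inflow Q(t) in m^3/s; positive into the lung.

    Inspiration (0 <= t <= T_in): ``Q = A (1 - exp(-t/tau))`` with A chosen
    so the inhaled volume is the tidal volume. Expiration: a passive
    decaying-exponential profile continuous at the transition whose
    integral returns exactly the tidal volume. Scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    if periodic:
        t = np.mod(t, w.period)
    elif np.any(t < 0) or np.any(t > w.period):
        raise ValueError(f"time outside the breath cycle [0, {w.period}] s; "
                         "pass periodic=True to wrap")
    tau = w.shape_tau
    q_insp = w._amplitude * (1.0 - np.exp(-t / tau))
    s = t - w.t_in
    tau_e = w._tau_ex
    with np.errstate(over="ignore"):
        q_exp = (w._q_end_insp - w._exp_coeff * s / tau_e) * np.exp(-np.maximum(s, 0.0) / tau_e)
    q = np.where(t <= w.t_in, q_insp, q_exp)
    return float(q) if q.ndim == 0 else q


def peak_inspiratory_flow(w: VentilatorWaveform) -> float:
    """Maximum of Q(t) over the cycle (attained at end inspiration)."""
    return w._q_end_insp


def build_airway_tree(morphology: pd.DataFrame, max_gn: int = 7,
                      air_viscosity: float = AIR_VISCOSITY) -> AirwayTree:
    """Assemble a symmetric tree from a per-generation morphology table.

    ``morphology`` needs columns ``gn``, ``radius_m``, ``length_m`` (wall
    thickness columns are ignored here; the tissue stage reads them).
    Branch counts follow the symmetric bifurcation rule ``2**gn``.
    """
    if max_gn < 0:
        raise ValueError("max_gn must be >= 0")
    df = morphology.set_index("gn")
    gens = []
    for gn in range(max_gn + 1):
        if gn not in df.index:
            raise ValueError(f"morphology table has no row for generation {gn}")
        row = df.loc[gn]
        gens.append(AirwayGeneration(gn=gn, radius=float(row["radius_m"]),
                                     length=float(row["length_m"]), count=2 ** gn))
    return AirwayTree(generations=tuple(gens), air_viscosity=air_viscosity)


def distribute_flow(tree: AirwayTree, q_inlet: float) -> np.ndarray:
    """Per-branch flow at each generation for a symmetric split.

    Mass conservation: ``count * per_branch == q_inlet`` at every
    generation, so the flow entering a bifurcation equals the sum leaving
    it.
    """
    counts = np.array([g.count for g in tree.generations], dtype=float)
    return q_inlet / counts


def branch_pressure_drop(g: AirwayGeneration, q_branch, mu_air: float = AIR_VISCOSITY):
    """Laminar (Poiseuille) pressure drop over one branch: 8 mu L q / (pi r^4)."""
    if g.radius <= 0:
        raise ValueError(f"generation {g.gn}: radius must be positive")
    return 8.0 * mu_air * g.length * np.asarray(q_branch, dtype=float) / (math.pi * g.radius ** 4)


@dataclass(frozen=True)
class PressureProfile:
    """Per-generation lumen pressure and per-branch flow over one breath.

    ``pressures[i, j]`` is the mean lumen pressure (Pa) of a generation-i
    segment at time ``times[j]``; ``branch_flows`` likewise holds the flow
    through a single branch. Pressures are gauge relative to the distal
    outlet boundary.
    """

    times: np.ndarray          # (n_t,)
    pressures: np.ndarray      # (n_gn, n_t)
    branch_flows: np.ndarray   # (n_gn, n_t)
    p_outlet: float = 0.0

    def peak_pressures(self) -> np.ndarray:
        """Peak-of-cycle lumen pressure per generation (the tissue-stage load)."""
        return self.pressures.max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        n_gn, n_t = self.pressures.shape
        return pd.DataFrame({
            "time_s": np.repeat(self.times, n_gn),
            "gn": np.tile(np.arange(n_gn), n_t),
            "pressure_Pa": self.pressures.T.ravel(),
            "flow_m3s": self.branch_flows.T.ravel(),
        })


def pressure_profile(tree: AirwayTree, w: VentilatorWaveform, p_outlet: float = 0.0,
                     n_samples: int = 200) -> PressureProfile:
    """Quasi-static Poiseuille-network pressures over one breath cycle.

    At each time sample the inlet flow is split symmetrically, the
    per-branch Poiseuille drops are evaluated, and node pressures are
    accumulated from the outlet boundary (distal end of the deepest
    generation, held at ``p_outlet``) upward. The reported per-generation
    pressure is the mean of the segment's proximal and distal node
    pressures. The network is linear in the inlet flow.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    times = np.linspace(0.0, w.period, n_samples)
    q_in = inlet_flow(times, w)
    counts = np.array([g.count for g in tree.generations], dtype=float)
    branch_flows = q_in[None, :] / counts[:, None]
    drops = np.stack([branch_pressure_drop(g, branch_flows[i], tree.air_viscosity)
                      for i, g in enumerate(tree.generations)])
    # distal node pressure of generation i = p_outlet + sum of drops below it
    below = np.cumsum(drops[::-1], axis=0)[::-1] - drops  # sum over j > i
    pressures = p_outlet + below + 0.5 * drops
    return PressureProfile(times=times, pressures=pressures,
                           branch_flows=branch_flows, p_outlet=p_outlet)
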