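"""Stochastic cellular-automata model of stretch-induced airway inflammation.

A rectangular lattice of epithelial cells (states: alive, dead, fibrosis)
is patrolled by two kinds of wandering immune agents. Macrophages sense
tissue stretch and release the pro-inflammatory cytokine TNF, suppressed
by the local anti-inflammatory cytokine TGF; fibroblasts release TGF in
proportion to local TNF. Both cytokines obey an explicit reaction-
diffusion update, dC/dt = D lap(C) - K C, with zero-flux boundaries.
Epithelial cells die with probability saturating in local TNF, heal with
probability saturating in local TGF, and cells dead long enough under
sustained TGF convert irreversibly to fibrosis (scar). Agents perform
chemotaxis-biased random walks toward TNF.

The per-step count of dead epithelial cells is the model's readout of
inflammation severity. All randomness flows through a single
``numpy.random.Generator`` per run, so a fixed seed reproduces a run
bit for bit.

Default parameters are a calibration: the lattice and rate constants are
chosen so that, driven by the wall strains the tissue stage computes for
the default airway tree, a high-strain (generation-4) episode peaks
before step 2000 and resolves by step 10000, a moderate (generation-6)
episode peaks about five-fold lower, and a low (generation-7) strain
stays below the activation threshold and produces no response at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ALIVE, DEAD, FIBROSIS = 0, 1, 2


@dataclass(frozen=True)
class Lattice:
    """Bounded (non-toroidal) 2D grid with 4-connected neighbourhood."""

    width: int = 100
    height: int = 100
    dx: float = 1.0

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("lattice must be at least 3x3")
        if self.dx <= 0:
            raise ValueError("site spacing must be positive")


@dataclass
class CytokineField:
    """One cytokine species on the lattice: concentration, diffusivity, decay."""

    species: str
    conc: np.ndarray          # (height, width), arbitrary units >= 0
    diffusivity: float        # sites^2 / step
    decay: float              # 1 / step
    dx: float = 1.0

    def total(self) -> float:
        return float(self.conc.sum())


@dataclass(frozen=True)
class WanderingAgent:
    kind: str                 # "macrophage" | "fibroblast"
    position: tuple[int, int]  # (row, col)


@dataclass(frozen=True)
class StrainInput:
    """Per-site strain driving the CA; static or sinusoidally fluctuating."""

    level: float | np.ndarray
    mode: str = "static"            # "static" | "fluctuating"
    amplitude: float = 0.0          # fractional amplitude when fluctuating
    period: float = 100.0           # steps

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.level) < 0):
            raise ValueError("strain must be >= 0")
        if self.mode not in ("static", "fluctuating"):
            raise ValueError(f"unknown strain mode {self.mode!r}")

    def at_step(self, step: int):
        if self.mode == "static":
            return self.level
        mod = 1.0 + self.amplitude * np.sin(2.0 * np.pi * step / self.period)
        return np.maximum(np.asarray(self.level) * mod, 0.0)


@dataclass(frozen=True)
class CAParams:
    """Rate constants and population sizes of the cellular model.

    Half-saturation constants are per interaction: ``c_half_damage`` for
    TNF-driven epithelial death, ``c_half_heal`` for TGF-driven healing,
    ``c_half_suppress`` for TGF suppression of macrophage TNF release and
    ``c_half_induce`` for TNF induction of fibroblast TGF release. The
    strain gate ramps smoothly from 0 at ``eps_act`` to 1 at ``eps_sat``.
    """

    n_macrophages: int = 50
    n_fibroblasts: int = 100
    eps_act: float = 1.9e-7        # activation threshold strain
    eps_sat: float = 6.0e-7        # strain at which the gate saturates
    p_damage_max: float = 0.08
    p_heal_max: float = 0.8
    p_tnf_max: float = 0.3
    p_tgf_max: float = 1.0
    c_half_damage: float = 1.0
    c_half_heal: float = 0.03
    c_half_suppress: float = 0.001
    c_half_induce: float = 0.02
    beta: float = 1.0              # chemotaxis sensitivity
    d_tnf: float = 0.1             # sites^2/step
    d_tgf: float = 0.1
    k_tnf: float = 0.06            # 1/step
    k_tgf: float = 2e-5
    tau_fib: int = 20              # steps dead before fibrosis is possible
    p_fib: float = 0.3
    theta_fib: float = 0.002       # TGF level required for fibrosis entry
    n_steps: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_damage_max", "p_heal_max", "p_tnf_max", "p_tgf_max", "p_fib"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("c_half_damage", "c_half_heal", "c_half_suppress", "c_half_induce"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eps_sat <= self.eps_act:
            raise ValueError("eps_sat must exceed eps_act")
        if self.n_macrophages < 0 or self.n_fibroblasts < 0:
            raise ValueError("agent counts must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class CAState:
    """Full mutable state of one CA run."""

    lattice: Lattice
    epi: np.ndarray            # (h, w) int8 of ALIVE/DEAD/FIBROSIS
    dead_since: np.ndarray     # (h, w) steps spent in the dead state
    tnf: CytokineField
    tgf: CytokineField
    mac_pos: np.ndarray        # (n_mac, 2) int rows/cols
    fib_pos: np.ndarray        # (n_fib, 2)
    step: int = 0

    @property
    def population(self) -> int:
        return self.epi.size

    def counts(self) -> tuple[int, int, int]:
        alive = int((self.epi == ALIVE).sum())
        dead = int((self.epi == DEAD).sum())
        fib = int((self.epi == FIBROSIS).sum())
        return alive, dead, fib


@dataclass
class InflammationTrace:
    """Per-step population counts and cytokine totals of one run."""

    alive: np.ndarray
    dead: np.ndarray
    fibrosis: np.ndarray
    tnf_total: np.ndarray
    tgf_total: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.dead.size - 1  # index 0 is the initial state

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(self.dead.size),
            "alive": self.alive, "dead": self.dead, "fibrosis": self.fibrosis,
            "tnf_total": self.tnf_total, "tgf_total": self.tgf_total,
        })


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def diffuse_decay(fld: CytokineField, dt: float = 1.0) -> CytokineField:
    """One explicit Euler step of dC/dt = D lap(C) - K C.

    Five-point Laplacian with zero-flux (reflecting) boundaries. The
    scheme is stable for D dt / dx^2 <= 0.25; violating that raises.
    Negative values can only arise from round-off and are clipped to 0.
    """
    cfl = fld.diffusivity * dt / fld.dx ** 2
    if cfl > 0.25 + 1e-12:
        raise ValueError(f"explicit diffusion unstable: D*dt/dx^2 = {cfl:.4g} > 0.25")
    c = fld.conc
    p = np.pad(c, 1, mode="edge")
    lap = (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * c) / fld.dx ** 2
    new = c + dt * (fld.diffusivity * lap - fld.decay * c)
    np.maximum(new, 0.0, out=new)
    return replace(fld, conc=new)


def activation_gate(strain, p: CAParams):
    """Smooth monotone gate in [0, 1]: 0 below eps_act, 1 above eps_sat.

    Cubic smoothstep on the normalised strain excess; this is the
    mechanotransduction link between tissue stretch and macrophage
    activation.
    """
    x = (np.asarray(strain, dtype=float) - p.eps_act) / (p.eps_sat - p.eps_act)
    x = np.clip(x, 0.0, 1.0)
    g = x * x * (3.0 - 2.0 * x)
    return float(g) if g.ndim == 0 else g


def release_probability(kind: str, local_tnf, local_tgf, p: CAParams, strain=None):
    """Per-step cytokine-release probability of a wandering agent.

    Macrophage TNF release is gated by strain and suppressed by TGF
    (higher when TGF is low); fibroblast TGF release saturates in TNF
    (higher when TNF is high). Both are bounded by their maxima.
    """
    if kind == "macrophage":
        gate = 1.0 if strain is None else activation_gate(strain, p)
        return p.p_tnf_max * gate * p.c_half_suppress / (p.c_half_suppress + np.asarray(local_tgf))
    if kind == "fibroblast":
        tnf = np.asarray(local_tnf, dtype=float)
        return p.p_tgf_max * tnf / (p.c_half_induce + tnf)
    raise ValueError(f"unknown agent kind {kind!r}")


def _move_agents(pos: np.ndarray, conc: np.ndarray, beta: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Chemotaxis-biased step for many agents at once.

    Each agent samples {stay, N, S, W, E} with weights proportional to
    exp(beta * C) at the candidate site; off-lattice candidates get zero
    weight. One uniform variate is consumed per agent.
    """
    if pos.size == 0:
        return pos
    h, w = conc.shape
    offsets = np.array([[0, 0], [-1, 0], [1, 0], [0, -1], [0, 1]])
    cand = pos[:, None, :] + offsets[None, :, :]        # (n, 5, 2)
    valid = ((cand[:, :, 0] >= 0) & (cand[:, :, 0] < h)
             & (cand[:, :, 1] >= 0) & (cand[:, :, 1] < w))
    rr = np.clip(cand[:, :, 0], 0, h - 1)
    cc = np.clip(cand[:, :, 1], 0, w - 1)
    logw = beta * conc[rr, cc]
    logw = logw - logw.max(axis=1, keepdims=True)
    wts = np.exp(logw) * valid
    cum = np.cumsum(wts, axis=1)
    u = rng.random(pos.shape[0]) * cum[:, -1]
    choice = (u[:, None] >= cum).sum(axis=1)
    return cand[np.arange(pos.shape[0]), choice]


def chemotaxis_step(agent: WanderingAgent, attractant: CytokineField, beta: float,
                    rng: np.random.Generator) -> WanderingAgent:
    """Single-agent chemotaxis move (wrapper over the vectorised walker)."""
    new = _move_agents(np.array([agent.position]), attractant.conc, beta, rng)
    return replace(agent, position=(int(new[0, 0]), int(new[0, 1])))


def damage_probability(local_tnf, p: CAParams):
    tnf = np.asarray(local_tnf, dtype=float)
    return p.p_damage_max * tnf / (p.c_half_damage + tnf)


def heal_probability(local_tgf, p: CAParams):
    tgf = np.asarray(local_tgf, dtype=float)
    return p.p_heal_max * tgf / (p.c_half_heal + tgf)


@dataclass(frozen=True)
class EpithelialCell:
    position: tuple[int, int]
    state: int = ALIVE
    dead_since: int = 0


def epithelial_update(cell: EpithelialCell, local_tnf: float, local_tgf: float,
                      p: CAParams, rng: np.random.Generator) -> EpithelialCell:
    """Probabilistic state transition of a single epithelial cell.

    alive -> dead with probability saturating in TNF; dead -> alive with
    probability saturating in TGF; a cell continuously dead for at least
    ``tau_fib`` steps under TGF above ``theta_fib`` converts to fibrosis
    with probability ``p_fib``. Fibrosis is absorbing.
    """
    if cell.state == ALIVE:
        if rng.random() < damage_probability(local_tnf, p):
            return replace(cell, state=DEAD, dead_since=0)
        return cell
    if cell.state == DEAD:
        if rng.random() < heal_probability(local_tgf, p):
            return replace(cell, state=ALIVE, dead_since=0)
        if (cell.dead_since >= p.tau_fib and local_tgf > p.theta_fib
                and rng.random() < p.p_fib):
            return replace(cell, state=FIBROSIS)
        return replace(cell, dead_since=cell.dead_since + 1)
    return cell  # fibrosis is absorbing


# ---------------------------------------------------------------------------
# the synchronous sweep
# ---------------------------------------------------------------------------

def init_state(params: CAParams, lattice: Lattice | None = None,
               rng: np.random.Generator | None = None) -> CAState:
    """All-alive epithelium, zero cytokines, agents placed uniformly."""
    lattice = lattice or Lattice()
    rng = rng or np.random.default_rng(params.seed)
    h, w = lattice.height, lattice.width
    mac = np.column_stack([rng.integers(0, h, params.n_macrophages),
                           rng.integers(0, w, params.n_macrophages)])
    fib = np.column_stack([rng.integers(0, h, params.n_fibroblasts),
                           rng.integers(0, w, params.n_fibroblasts)])
    mk = lambda name, d, k: CytokineField(name, np.zeros((h, w)), d, k, lattice.dx)
    return CAState(lattice=lattice,
                   epi=np.full((h, w), ALIVE, dtype=np.int8),
                   dead_since=np.zeros((h, w), dtype=np.int32),
                   tnf=mk("TNF", params.d_tnf, params.k_tnf),
                   tgf=mk("TGF", params.d_tgf, params.k_tgf),
                   mac_pos=mac.astype(np.int64), fib_pos=fib.astype(np.int64))


def ca_step(state: CAState, strain: StrainInput, p: CAParams,
            rng: np.random.Generator) -> CAState:
    """One synchronous sweep: move, release, diffuse, epithelial update.

    The sub-step order is fixed (macrophage moves, fibroblast moves,
    macrophage TNF release, fibroblast TGF release, diffusion of both
    fields, epithelial transitions) so a run is fully determined by the
    seed. The epithelial population count is conserved; states only
    relabel. The state is updated in place and returned.
    """
    s_field = np.broadcast_to(np.asarray(strain.at_step(state.step), dtype=float),
                              state.epi.shape)
    # 1) chemotaxis: both wandering kinds climb the TNF (injury) field
    state.mac_pos = _move_agents(state.mac_pos, state.tnf.conc, p.beta, rng)
    state.fib_pos = _move_agents(state.fib_pos, state.tnf.conc, p.beta, rng)
    # 2) cytokine release: one unit bolus at the agent's site
    if state.mac_pos.size:
        mr, mc = state.mac_pos[:, 0], state.mac_pos[:, 1]
        pr = release_probability("macrophage", None, state.tgf.conc[mr, mc], p,
                                 strain=s_field[mr, mc])
        fire = rng.random(mr.size) < pr
        np.add.at(state.tnf.conc, (mr[fire], mc[fire]), 1.0)
    if state.fib_pos.size:
        fr, fc = state.fib_pos[:, 0], state.fib_pos[:, 1]
        pr = release_probability("fibroblast", state.tnf.conc[fr, fc], None, p)
        fire = rng.random(fr.size) < pr
        np.add.at(state.tgf.conc, (fr[fire], fc[fire]), 1.0)
    # 3) cytokine kinetics
    state.tnf = diffuse_decay(state.tnf)
    state.tgf = diffuse_decay(state.tgf)
    # 4) epithelial transitions (synchronous, from the post-diffusion fields)
    u_dam = rng.random(state.epi.shape)
    u_heal = rng.random(state.epi.shape)
    u_fib = rng.random(state.epi.shape)
    alive = state.epi == ALIVE
    dead = state.epi == DEAD
    dies = alive & (u_dam < damage_probability(state.tnf.conc, p))
    heals = dead & (u_heal < heal_probability(state.tgf.conc, p))
    fibroses = (dead & ~heals & (state.dead_since >= p.tau_fib)
                & (state.tgf.conc > p.theta_fib) & (u_fib < p.p_fib))
    state.epi[dies] = DEAD
    state.dead_since[dies] = 0
    state.epi[heals] = ALIVE
    state.dead_since[heals] = 0
    state.epi[fibroses] = FIBROSIS
    still_dead = dead & ~heals & ~fibroses
    state.dead_since[still_dead] += 1
    state.step += 1
    return state


def run_inflammation(strain: StrainInput, p: CAParams, n_steps: int | None = None,
                     seed: int | None = None,
                     lattice: Lattice | None = None) -> InflammationTrace:
    """Iterate the CA and record counts and cytokine totals per step.

    The trace includes the initial state at index 0, so it has
    ``n_steps + 1`` entries. ``seed`` overrides ``p.seed``.
    """
    n_steps = p.n_steps if n_steps is None else n_steps
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(p.seed if seed is None else seed)
    state = init_state(p, lattice, rng)
    n = n_steps + 1
    alive = np.empty(n, dtype=np.int64)
    dead = np.empty(n, dtype=np.int64)
    fib = np.empty(n, dtype=np.int64)
    tnf = np.empty(n)
    tgf = np.empty(n)
    for i in range(n):
        alive[i], dead[i], fib[i] = state.counts()
        tnf[i], tgf[i] = state.tnf.total(), state.tgf.total()
        if i < n_steps:
            ca_step(state, strain, p, rng)
    return InflammationTrace(alive=alive, dead=dead, fibrosis=fib,
                             tnf_total=tnf, tgf_total=tgf)


@dataclass
class EnsembleSummary:
    """Seeded-replicate ensemble of inflammation runs."""

    traces: list[InflammationTrace]
    mean_dead: np.ndarray
    std_dead: np.ndarray
    mean_fibrosis: np.ndarray
    peak_heights: np.ndarray
    peak_steps: np.ndarray

    @property
    def cv_peak(self) -> float:
        """Coefficient of variation of the peak dead count across replicates."""
        m = self.peak_heights.mean()
        return float(self.peak_heights.std(ddof=1) / m) if m > 0 else 0.0


def run_ensemble(strain: StrainInput, p: CAParams, n_steps: int | None = None,
                 n_reps: int = 20, seed: int = 0,
                 lattice: Lattice | None = None) -> EnsembleSummary:
    """Independent replicates with counter-based child seeds.

    Replicate ``i`` is seeded from ``SeedSequence((seed, i))``, so the
    ensemble is reproducible and replicates are statistically
    independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    traces = []
    for i in range(n_reps):
        child = np.random.SeedSequence((seed, i))
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        traces.append(run_inflammation(strain, p, n_steps=n_steps,
                                       seed=rep_seed, lattice=lattice))
    dead = np.stack([t.dead for t in traces]).astype(float)
    fib = np.stack([t.fibrosis for t in traces]).astype(float)
    return EnsembleSummary(traces=traces,
                           mean_dead=dead.mean(axis=0),
                           std_dead=dead.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(dead.shape[1]),
                           mean_fibrosis=fib.mean(axis=0),
                           peak_heights=dead.max(axis=1),
                           peak_steps=dead.argmax(axis=1))
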