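"""Langevin dynamics with constant-velocity steered pulling.

The integrator is a BAOAB splitting of Langevin dynamics; with the
thermostat off (gamma = 0, T = 0) it reduces to velocity Verlet.  One
anchor residue is harmonically tethered to a fixed point and the other to
a point moving at constant speed along the initial anchor-anchor axis; the
instantaneous spring force (reported in pN) against the chain extension is
the primary observable.  Extension is defined as the current anchor-anchor
distance minus its value in the native conformation, so it starts near zero
and is comparable across disulfide treatments.

Cysteine-pair distances are logged for every saved frame; the binary
bond state uses the 5.5 Å Cβ-proxy criterion with a two-saved-frame
hysteresis to suppress flicker at the boundary, and break/form events are
derived from the debounced states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .potentials import CGSystem, GoParams, RedoxModel, build_system, minimize_energy
from .topology import SS_CUTOFF, ChainTopology
from .units import AKMA_FS, KB, KCAL_PER_MOL_ANG_TO_PN, MTU_FS


class NumericalBlowupError(RuntimeError):
    """Trajectory aborted: coordinates exceeded the sanity bound."""


@dataclass(frozen=True)
class SMDProtocol:
    """Steered-MD protocol.

    speed is in Å/MTU on the coarse-grained grid (0.0005-0.02 in the source
    experiments); spring_k in kcal/mol/Å²; friction_scale multiplies the
    base friction of ``gamma_base_ps`` (1/ps); dt_fs = 0.489 fs is one
    hundredth of an MTU.  ``n_equil`` thermalization steps follow the
    1000-step energy minimization before pulling starts.
    """

    speed: float = 0.02
    spring_k: float = 1.0
    anchors: tuple | None = None       # residue ordinals; default: topology's
    temperature: float = 300.0
    friction_scale: float = 0.01
    gamma_base_ps: float = 5.0
    dt_fs: float = 0.489
    n_steps: int = 100_000
    save_every: int = 200
    n_equil: int = 10_000
    n_min: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.speed < 0 or self.spring_k <= 0:
            raise ValueError("require speed >= 0 and spring_k > 0")
        if self.dt_fs <= 0 or self.save_every < 1:
            raise ValueError("require dt_fs > 0 and save_every >= 1")


@dataclass
class TrajectoryFrame:
    step: int
    time_fs: float
    coordinates: np.ndarray
    extension: float
    force_pN: float
    ss_distances: dict
    ss_bonded: dict
    energy: dict


@dataclass
class BondEvent:
    pair: tuple
    kind: str          # 'break' | 'form'
    step: int
    extension: float


@dataclass
class Trajectory:
    """Saved frames of one run, in array form."""

    topology: ChainTopology
    protocol: SMDProtocol
    mode: str
    steps: np.ndarray
    time_fs: np.ndarray
    xs: np.ndarray                    # (n_frames, n_beads, 3), float32
    extension: np.ndarray             # Å
    force_pN: np.ndarray
    e_pot: np.ndarray
    e_ss: np.ndarray
    ss_pairs: list                    # residue-ordinal pairs (all cysteine pairs)
    ss_dist: np.ndarray               # (n_frames, n_pairs)
    bonded: np.ndarray                # debounced states, bool
    events: list = field(default_factory=list)
    native_anchor_sep: float = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    def frames(self):
        for k in range(self.n_frames):
            yield TrajectoryFrame(
                step=int(self.steps[k]), time_fs=float(self.time_fs[k]),
                coordinates=self.xs[k].astype(float),
                extension=float(self.extension[k]),
                force_pN=float(self.force_pN[k]),
                ss_distances={p: float(self.ss_dist[k, m])
                              for m, p in enumerate(self.ss_pairs)},
                ss_bonded={p: bool(self.bonded[k, m])
                           for m, p in enumerate(self.ss_pairs)},
                energy={"potential": float(self.e_pot[k]),
                        "ss": float(self.e_ss[k])})


def langevin_step(x, v, mass, force_fn, dt, kT, gamma, rng):
    """One BAOAB step (reference implementation; the production loop is the
    compiled kernel).  Returns updated (x, v, force at new x).

    With gamma = 0 or kT = 0 the O-step is the identity and the scheme is
    velocity Verlet.
    """
    if dt <= 0 or gamma < 0:
        raise ValueError("require dt > 0 and gamma >= 0")
    f = force_fn(x)
    v = v + 0.5 * dt * f / mass
    x = x + 0.5 * dt * v
    if gamma > 0 and kT > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(kT * (1 - c1 * c1) / mass)
        v = c1 * v + c2 * rng.standard_normal(np.shape(v))
    x = x + 0.5 * dt * v
    if np.max(np.abs(x)) > 1e6:
        raise NumericalBlowupError(f"|x| exceeded 1e6 at max {np.max(np.abs(x)):.3g}")
    f = force_fn(x)
    v = v + 0.5 * dt * f / mass
    return x, v, f


def _derive_seed(seed: int, salt: int) -> int:
    return int((seed * 2654435761 + salt * 97531) % (2 ** 31 - 1))


def _debounce(raw: np.ndarray, persistence: int = 2) -> np.ndarray:
    """Debounced bond states: a flip registers only after ``persistence``
    consecutive frames of the opposite raw state."""
    out = np.empty_like(raw)
    state = bool(raw[0])
    run = 0
    for k in range(len(raw)):
        if bool(raw[k]) != state:
            run += 1
            if run >= persistence:
                state = bool(raw[k])
                run = 0
        else:
            run = 0
        out[k] = state
    return out


def _events_from_states(pairs, bonded, steps, extension):
    events = []
    for m, pair in enumerate(pairs):
        st = bonded[:, m]
        for k in range(1, len(st)):
            if st[k] != st[k - 1]:
                events.append(BondEvent(
                    pair=pair, kind=("break" if st[k - 1] else "form"),
                    step=int(steps[k]), extension=float(extension[k])))
    events.sort(key=lambda e: e.step)
    return events


def _run(topology: ChainTopology, native_coords: np.ndarray, go: GoParams,
         redox: RedoxModel, protocol: SMDProtocol, pulling: bool):
    n_res = topology.n_residues
    anchors = protocol.anchors if protocol.anchors is not None else topology.anchors
    for a in anchors:
        if not (0 <= a < n_res):
            raise ValueError(f"anchor residue {a} outside chain of {n_res} residues")
    if anchors[0] == anchors[1]:
        raise ValueError("anchors must be distinct")
    ai, aj = int(topology.bb_index[anchors[0]]), int(topology.bb_index[anchors[1]])

    system = build_system(topology, go, redox, native_coords=native_coords)
    kT = KB * protocol.temperature
    dt = protocol.dt_fs / AKMA_FS
    gamma = protocol.gamma_base_ps * protocol.friction_scale * 1e-3 * AKMA_FS
    speed = protocol.speed / MTU_FS * AKMA_FS   # Å per internal time

    # preparation: energy minimization, then thermalization
    x = minimize_energy(np.array(native_coords, dtype=float), system,
                        maxiter=protocol.n_min, gtol=1e-5)
    rng = np.random.default_rng(_derive_seed(protocol.seed, 1))
    v = rng.standard_normal(x.shape) * np.sqrt(kT / system.masses[:, None]) \
        if kT > 0 else np.zeros_like(x)

    cys = sorted(topology.cysteines)
    log_resid_pairs = [(cys[a], cys[b]) for a in range(len(cys))
                       for b in range(a + 1, len(cys))]
    log_pairs = np.array([(topology.cbeta_proxy_index(i), topology.cbeta_proxy_index(j))
                          for i, j in log_resid_pairs], dtype=np.int64).reshape(-1, 2)

    native_sep = float(np.linalg.norm(
        np.asarray(native_coords)[ai] - np.asarray(native_coords)[aj]))

    def launch(x, v, n_steps, seed, pull_on, fix_pt, mov_pt0, pull_dir):
        ns = n_steps // protocol.save_every + 1
        out_x = np.empty((ns, system.n_beads, 3), dtype=np.float32)
        out_ext = np.empty(ns)
        out_force = np.empty(ns)
        out_epot = np.empty(ns)
        out_ess = np.empty(ns)
        out_ssd = np.empty((ns, max(len(log_pairs), 1)))
        n_saved = _kernels.integrate(
            x, v, system.masses, dt, n_steps, protocol.save_every, gamma, kT,
            seed, *system.kernel_args(),
            1 if pull_on else 0, ai, aj, fix_pt, mov_pt0, pull_dir,
            speed, protocol.spring_k, native_sep,
            log_pairs, out_x, out_ext, out_force, out_epot, out_ess, out_ssd)
        if n_saved <= 0:
            raise NumericalBlowupError(
                f"trajectory aborted after {-n_saved} saved frames: "
                "coordinates exceeded 1e6 Å")
        return n_saved, out_x, out_ext, out_force, out_epot, out_ess, out_ssd

    zero3 = np.zeros(3)
    if protocol.n_equil > 0 and kT > 0:
        # thermalization: x and v are updated in place by the kernel
        launch(x, v, protocol.n_equil, _derive_seed(protocol.seed, 2),
               False, zero3, zero3, zero3)

    # pulling axis: the native anchor-anchor direction (deterministic
    # across seeds); the fixed/moving points are the prepared anchors
    axis = np.asarray(native_coords)[aj] - np.asarray(native_coords)[ai]
    axis = axis / np.linalg.norm(axis)
    fix_pt = x[ai].copy()
    mov_pt0 = x[aj].copy()

    n_saved, out_x, out_ext, out_force, out_epot, out_ess, out_ssd = launch(
        x, v, protocol.n_steps, _derive_seed(protocol.seed, 3),
        pulling and protocol.speed > 0, fix_pt, mov_pt0, axis)

    sl = slice(0, n_saved)
    steps = np.arange(n_saved) * protocol.save_every
    raw = out_ssd[sl] < SS_CUTOFF
    bonded = np.empty_like(raw) if raw.size else raw
    for m in range(raw.shape[1] if len(log_resid_pairs) else 0):
        bonded[:, m] = _debounce(raw[:, m])
    traj = Trajectory(
        topology=topology, protocol=protocol, mode=redox.mode,
        steps=steps, time_fs=steps * protocol.dt_fs,
        xs=out_x[sl], extension=out_ext[sl],
        force_pN=out_force[sl] * KCAL_PER_MOL_ANG_TO_PN,
        e_pot=out_epot[sl], e_ss=out_ess[sl],
        ss_pairs=log_resid_pairs,
        ss_dist=out_ssd[sl] if len(log_resid_pairs) else out_ssd[sl, :0],
        bonded=bonded if len(log_resid_pairs) else raw,
        native_anchor_sep=native_sep)
    if redox.mode == "static":
        traj.events = []
    else:
        traj.events = _events_from_states(log_resid_pairs, traj.bonded,
                                          steps, traj.extension)
    return traj, traj.events


def run_smd(topology: ChainTopology, native_coords: np.ndarray,
            go: GoParams | None = None, redox: RedoxModel | None = None,
            protocol: SMDProtocol | None = None):
    """Steered run: minimization + thermalization, then constant-velocity
    pulling.  Returns (Trajectory, list of BondEvents)."""
    return _run(topology, native_coords, go or GoParams(),
                redox or RedoxModel(), protocol or SMDProtocol(), pulling=True)


def run_equilibrium(topology: ChainTopology, native_coords: np.ndarray,
                    go: GoParams | None = None, redox: RedoxModel | None = None,
                    protocol: SMDProtocol | None = None):
    """Unbiased run (no pulling); baseline for RMSD/Rg/RMSF analyses."""
    proto = protocol or SMDProtocol()
    traj, _ = _run(topology, native_coords, go or GoParams(),
                   redox or RedoxModel(), proto, pulling=False)
    return traj


def sample_pair_distances(dyn, tether_k: float = 0.3, tether_r0: float = 5.0,
                          temperature: float = 300.0, gamma_ps: float = 20.0,
                          dt_fs: float = 0.489, n_samples: int = 1_000_000,
                          save_every: int = 20, seed: int = 0) -> np.ndarray:
    """Equilibrium distance samples of one tethered cysteine pair.

    Two free beads interact through the dynamic disulfide double well plus a
    weak harmonic tether k_t (r - r0_t)² that keeps the sampler bounded; the
    stationary distribution is p(r) ∝ r² exp(-(U_dyn(r) + U_tether(r))/kT).
    Used to validate the thermostat against direct numeric integration.
    """
    from .potentials import BEAD_MASS, RedoxModel, TripletRepulsionParams

    kT = KB * temperature
    dt = dt_fs / AKMA_FS
    gamma = gamma_ps * 1e-3 * AKMA_FS
    n_steps = n_samples * save_every
    x = np.array([[0.0, 0.0, 0.0], [dyn.r_bond, 0.0, 0.0]])
    rng = np.random.default_rng(_derive_seed(seed, 11))
    masses = np.full(2, BEAD_MASS)
    v = rng.standard_normal((2, 3)) * np.sqrt(kT / masses[:, None])

    empty2 = np.zeros((0, 2), dtype=np.int64)
    emptyf = np.zeros(0)
    ss_pairs = np.array([[0, 1]], dtype=np.int64)
    cys_sc = np.array([0, 1], dtype=np.int64)
    extra_pairs = np.array([[0, 1]], dtype=np.int64)
    ns = n_steps // save_every + 1
    out_x = np.empty((ns, 2, 3), dtype=np.float32)
    out_ext = np.empty(ns)
    out_force = np.empty(ns)
    out_epot = np.empty(ns)
    out_ess = np.empty(ns)
    out_ssd = np.empty((ns, 1))
    zero3 = np.zeros(3)
    n_saved = _kernels.integrate(
        x, v, masses, dt, n_steps, save_every, gamma, kT,
        _derive_seed(seed, 13),
        empty2, emptyf, emptyf,            # bonds
        empty2, emptyf, emptyf,            # contacts
        np.zeros((0, 4), dtype=np.int64), emptyf, 0.0,   # dihedrals
        empty2, 0, 4.0, 0.0,               # excluded volume (off)
        _kernels.MODE_DYNAMIC, ss_pairs, np.array([dyn.r_bond]), 0.0,
        dyn.as_array, TripletRepulsionParams().as_array,
        RedoxModel().restraint.as_array, cys_sc,
        extra_pairs, np.array([tether_k]), np.array([tether_r0]),
        0, 0, 1, zero3, zero3, zero3, 0.0, 1.0, dyn.r_bond,
        ss_pairs, out_x, out_ext, out_force, out_epot, out_ess, out_ssd)
    if n_saved <= 0:
        raise NumericalBlowupError("pair sampler diverged")
    return out_ssd[1:n_saved, 0]   # drop the deterministic initial frame


# ---------------------------------------------------------------------------
# text logs
# ---------------------------------------------------------------------------

def write_force_log(traj: Trajectory, path, header_extra: str = "") -> None:
    """TSV force/extension/bond-state log, one row per saved frame."""
    cols = ["step", "time_fs", "extension_A", "force_pN", "e_pot", "e_ss"]
    for i, j in traj.ss_pairs:
        cols += [f"d_{i + 1}_{j + 1}", f"b_{i + 1}_{j + 1}"]
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write(f"# mode={traj.mode} speed={traj.protocol.speed} "
                 f"seed={traj.protocol.seed}\n")
        fh.write("\t".join(cols) + "\n")
        for k in range(traj.n_frames):
            row = [f"{traj.steps[k]}", f"{traj.time_fs[k]:.3f}",
                   f"{traj.extension[k]:.4f}", f"{traj.force_pN[k]:.4f}",
                   f"{traj.e_pot[k]:.4f}", f"{traj.e_ss[k]:.4f}"]
            for m in range(len(traj.ss_pairs)):
                row += [f"{traj.ss_dist[k, m]:.4f}", f"{int(traj.bonded[k, m])}"]
            fh.write("\t".join(row) + "\n")


def write_events(events, path, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("res_i\tres_j\tkind\tstep\textension_A\n")
        for e in events:
            fh.write(f"{e.pair[0] + 1}\t{e.pair[1] + 1}\t{e.kind}\t{e.step}\t"
                     f"{e.extension:.4f}\n")


def write_trajectory_xyz(traj: Trajectory, path, stride: int = 1) -> None:
    """Plain multi-frame XYZ (element C for every bead)."""
    n = traj.xs.shape[1]
    with open(path, "w") as fh:
        for k in range(0, traj.n_frames, stride):
            fh.write(f"{n}\nstep={traj.steps[k]} extension={traj.extension[k]:.3f}\n")
            for a in range(n):
                x, y, z = traj.xs[k, a]
                fh.write(f"C {x:.4f} {y:.4f} {z:.4f}\n")


def write_trajectory_pdb(traj: Trajectory, path, stride: int = 1) -> None:
    """Multi-model PDB of saved frames."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    topo = traj.topology
    frames = traj.xs[::stride].astype(np.float32)
    arr = struc.AtomArray(topo.n_beads)
    arr.chain_id = np.full(topo.n_beads, "A")
    arr.res_id = np.array([b.index + 1 for b in topo.beads])
    arr.res_name = np.array([b.residue_name for b in topo.beads])
    arr.atom_name = np.array(
        ["CA" if b.kind == "backbone-center" else "CB" for b in topo.beads])
    arr.element = np.full(topo.n_beads, "C")
    arr.hetero = np.zeros(topo.n_beads, dtype=bool)
    stack = struc.from_template(arr, frames)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
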