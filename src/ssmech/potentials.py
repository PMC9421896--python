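"""Energy terms for the coarse-grained mechanical-unfolding model.

The background stability model is a structure-based (Gō) potential: stiff
harmonic backbone and side-attachment bonds, 12-10 native-contact wells,
a quartic excluded-volume repulsion, and cosine pseudo-dihedrals restrained
to their native values.  On top of it sit the disulfide treatments:

* ``dynamic`` — a distance double-well between *every* cysteine pair
  (bonded minimum near 4 Å whose depth encodes the redox potential of the
  medium: 5.5 kcal/mol for a weakly oxidizing, 11.0 kcal/mol for a highly
  oxidizing environment; a shallow contact minimum near 6.5 Å that is left
  untouched by the redox setting), plus a triplet repulsion that makes a
  cysteine bonded to two partners at once energetically forbidden;
* ``static`` — native crosslinks as permanent harmonic bonds;
* ``restraint`` — a flat-bottom restraint on native crosslinks that turns
  into a constant-force linear tail beyond its outer switch distance, so a
  "bond" can break at a well-defined mimicking force (556 pN at defaults);
* ``none`` — no disulfide term at all (reducing environment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

from . import _kernels
from ._kernels import MODE_DYNAMIC, MODE_NONE, MODE_RESTRAINT, MODE_STATIC

if TYPE_CHECKING:  # pragma: no cover
    from .topology import ChainTopology

MODES = {"none": MODE_NONE, "dynamic": MODE_DYNAMIC,
         "static": MODE_STATIC, "restraint": MODE_RESTRAINT}

#: uniform bead mass, amu: the ~110 amu of an average residue split evenly
#: between its backbone and side interaction centers
BEAD_MASS = 55.0


class OverlappingBeadsError(ValueError):
    """Two beads closer than the hard-core limit."""


@dataclass(frozen=True)
class GoParams:
    """Structure-based background potential parameters.

    bond_k in kcal/mol/Å², eps_contact (12-10 well depth) in kcal/mol,
    sigma_ev / eps_ev the excluded-volume radius (Å) and strength, and
    k_dih the pseudo-dihedral stiffness (kcal/mol).
    """

    bond_k: float = 100.0
    eps_contact: float = 1.0
    sigma_ev: float = 4.0
    eps_ev: float = 3.0
    k_dih: float = 0.3

    def __post_init__(self):
        if self.sigma_ev <= 0:
            raise ValueError("sigma_ev must be > 0")
        for name in ("bond_k", "eps_contact", "eps_ev", "k_dih"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _default_a_core(r_bond: float) -> float:
    # repulsive core sized so it contributes 0.05 kcal/mol at the bonded
    # minimum, keeping U(r_bond) within 2% of -D_bond for D_bond >= 2.5
    return 0.05 * r_bond ** 12


@dataclass(frozen=True)
class DynamicSSParams:
    """Breakable-disulfide double-well parameters.

    ``D_bond`` (kcal/mol) is the depth of the bonded well at ``r_bond`` and
    encodes the redox environment: 5.5 for weakly and 11.0 for highly
    oxidizing conditions.  The contact minimum (``D_contact`` at
    ``r_contact``) is independent of the redox setting.
    """

    D_bond: float = 5.5
    r_bond: float = 4.0
    s_bond: float = 0.4
    D_contact: float = 1.0
    r_contact: float = 6.5
    s_contact: float = 0.8
    A_core: float | None = None

    def __post_init__(self):
        if not (self.D_bond > self.D_contact > 0):
            raise ValueError("require D_bond > D_contact > 0")
        if not (self.r_contact > self.r_bond > 0):
            raise ValueError("require r_contact > r_bond > 0")
        if self.A_core is None:
            object.__setattr__(self, "A_core", _default_a_core(self.r_bond))

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.A_core, self.D_bond, self.r_bond, self.s_bond,
                         self.D_contact, self.r_contact, self.s_contact])


@dataclass(frozen=True)
class TripletRepulsionParams:
    """Triplet repulsion preventing one cysteine from binding two partners.

    U = a * s(r_ki) * s(r_kj) with s(r) = (1 + exp(b (r - c)))^(-d): the
    penalty is ``a`` when both partner distances are deep in bonding range
    and decays to zero once either partner leaves it.  All four parameters
    are user-tunable; the defaults make a doubly-bonded cysteine cost more
    than one bonded-well depth even in the highly oxidizing setting.
    """

    a: float = 30.0
    b: float = 4.0
    c: float = 5.0
    d: float = 1.0

    def __post_init__(self):
        if self.a < 0 or self.b <= 0 or self.c <= 0 or self.d <= 0:
            raise ValueError("invalid triplet-repulsion parameters")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])


@dataclass(frozen=True)
class RestraintParams:
    """Flat-bottom breaking restraint: harmonic below r1 and on [r2, r3],
    zero on [r1, r2], linear beyond r3 with constant force 2 k (r3 - r2)."""

    k: float = 4.0
    r1: float = 1.8
    r2: float = 3.0
    r3: float = 4.0

    def __post_init__(self):
        if not (self.r1 < self.r2 < self.r3):
            raise ValueError("require r1 < r2 < r3")
        if self.k <= 0:
            raise ValueError("require k > 0")

    @property
    def tail_force(self) -> float:
        """Constant tail-force magnitude, kcal/mol/Å."""
        return 2.0 * self.k * (self.r3 - self.r2)

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.k, self.r1, self.r2, self.r3])


@dataclass(frozen=True)
class RedoxModel:
    """Disulfide treatment: mode plus the parameter sets it draws on."""

    mode: str = "none"
    dyn: DynamicSSParams = field(default_factory=DynamicSSParams)
    triplet: TripletRepulsionParams = field(default_factory=TripletRepulsionParams)
    restraint: RestraintParams = field(default_factory=RestraintParams)
    k_static: float = 100.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {sorted(MODES)}")

    def with_depth(self, D_bond: float) -> "RedoxModel":
        """Return a copy with the bonded-well depth (redox setting) changed."""
        return replace(self, dyn=replace(self.dyn, D_bond=D_bond, A_core=None))


# ---------------------------------------------------------------------------
# scalar potential wrappers
# ---------------------------------------------------------------------------

def u_dynss(r, p: DynamicSSParams | None = None):
    """Dynamic-disulfide double well: (energy, radial force -dU/dr).

    Accepts scalars or arrays of distances (Å).
    """
    p = p or DynamicSSParams()
    rs = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(rs <= 0):
        raise ValueError("distance must be > 0")
    u = np.empty_like(rs)
    f = np.empty_like(rs)
    for i, ri in enumerate(rs):
        u[i], f[i] = _kernels.u_dynss_scalar(
            ri, p.A_core, p.D_bond, p.r_bond, p.s_bond,
            p.D_contact, p.r_contact, p.s_contact)
    if np.isscalar(r):
        return float(u[0]), float(f[0])
    return u, f


def u_flatbottom(r, p: RestraintParams | None = None):
    """Flat-bottom restraint: (energy, radial force -dU/dr)."""
    p = p or RestraintParams()
    rs = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(rs <= 0):
        raise ValueError("distance must be > 0")
    u = np.empty_like(rs)
    f = np.empty_like(rs)
    for i, ri in enumerate(rs):
        u[i], f[i] = _kernels.u_flatbottom_scalar(ri, p.k, p.r1, p.r2, p.r3)
    if np.isscalar(r):
        return float(u[0]), float(f[0])
    return u, f


def u_sss_triplet(r_ki: float, r_kj: float,
                  p: TripletRepulsionParams | None = None) -> float:
    """Triplet-repulsion energy for cysteine k with candidate partners i, j."""
    p = p or TripletRepulsionParams()
    if r_ki <= 0 or r_kj <= 0:
        raise ValueError("distances must be > 0")
    u, _, _ = _kernels.u_sss_scalar(r_ki, r_kj, p.a, p.b, p.c, p.d)
    return float(u)


# ---------------------------------------------------------------------------
# compiled system
# ---------------------------------------------------------------------------

@dataclass
class CGSystem:
    """Array form of a topology + parameter set, ready for the kernels."""

    n_beads: int
    masses: np.ndarray
    bonds: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    contacts: np.ndarray
    contact_r0: np.ndarray
    contact_eps: np.ndarray
    dihedrals: np.ndarray
    dih_phi0: np.ndarray
    k_dih: float
    ev_pairs: np.ndarray       # static excluded-volume pair list
    sigma_ev: float
    eps_ev: float
    mode: int
    ss_pairs: np.ndarray       # bead-index pairs carrying the SS term
    ss_pair_resids: list       # residue-ordinal pairs aligned with ss_pairs
    ss_r0: np.ndarray          # static-mode equilibrium distances
    k_static: float
    d_par: np.ndarray
    t_par: np.ndarray
    r_par: np.ndarray
    cys_sc: np.ndarray         # side-center (Cβ-proxy) bead index per cysteine
    extra_pairs: np.ndarray
    extra_k: np.ndarray
    extra_r0: np.ndarray

    def kernel_args(self):
        return (self.bonds, self.bond_k, self.bond_r0,
                self.contacts, self.contact_r0, self.contact_eps,
                self.dihedrals, self.dih_phi0, self.k_dih,
                self.ev_pairs, self.ev_pairs.shape[0], self.sigma_ev, self.eps_ev,
                self.mode, self.ss_pairs, self.ss_r0, self.k_static,
                self.d_par, self.t_par, self.r_par, self.cys_sc,
                self.extra_pairs, self.extra_k, self.extra_r0)


def build_system(topology: "ChainTopology", go: GoParams,
                 redox: RedoxModel | None = None,
                 native_coords: np.ndarray | None = None,
                 extra_restraints=None) -> CGSystem:
    """Compile a :class:`ChainTopology` + parameters into kernel arrays.

    ``native_coords`` is needed for static-mode equilibrium crosslink
    distances (falls back on the dynamic bonded-well position).
    ``extra_restraints`` is a list of (bead_i, bead_j, k, r0) auxiliary
    harmonic terms.
    """
    redox = redox or RedoxModel()
    n = topology.n_beads
    mode = MODES[redox.mode]

    bonds = []
    for i, j, r0 in topology.all_bonds():
        bonds.append((i, j, r0))
    bonds_arr = np.array([(b[0], b[1]) for b in bonds], dtype=np.int64).reshape(-1, 2)
    bond_r0 = np.array([b[2] for b in bonds], dtype=float)
    bond_k = np.full(len(bonds), go.bond_k, dtype=float)

    c_idx, c_r0, c_eps = [], [], []
    for c in topology.native_contacts:
        bi, bj = topology.contact_bead_indices(c)
        c_idx.append((bi, bj))
        c_r0.append(c.r0)
        c_eps.append(go.eps_contact)
    contacts_arr = np.array(c_idx, dtype=np.int64).reshape(-1, 2)
    contact_r0 = np.array(c_r0, dtype=float)
    contact_eps = np.array(c_eps, dtype=float)

    dih = np.array([d[:4] for d in topology.native_dihedrals],
                   dtype=np.int64).reshape(-1, 4)
    phi0 = np.array([d[4] for d in topology.native_dihedrals], dtype=float)

    # exclusions: bonded pairs, near-neighbour residues, native-contact pairs
    excl = np.zeros((n, n), dtype=np.uint8)
    resid = topology.bead_residues()
    for i in range(n):
        for j in range(n):
            if abs(resid[i] - resid[j]) <= 1:
                excl[i, j] = 1
    for i, j in bonds_arr:
        excl[i, j] = excl[j, i] = 1
    for i, j in contacts_arr:
        excl[i, j] = excl[j, i] = 1

    cys = sorted(topology.cysteines)
    cys_sc = np.array([topology.cbeta_proxy_index(c) for c in cys], dtype=np.int64)
    if mode == MODE_DYNAMIC:
        ss_resids = [(cys[a], cys[b]) for a in range(len(cys))
                     for b in range(a + 1, len(cys))]
        # the dynss core replaces generic excluded volume for these pairs
        for a in range(len(cys_sc)):
            for b in range(len(cys_sc)):
                if a != b:
                    excl[cys_sc[a], cys_sc[b]] = 1
    elif mode in (MODE_STATIC, MODE_RESTRAINT):
        if not topology.crosslinks:
            raise ValueError(f"mode={redox.mode!r} requires a non-empty crosslink list")
        ss_resids = [tuple(p) for p in topology.crosslinks]
    else:
        ss_resids = []
    ss_pairs = np.array([(topology.cbeta_proxy_index(i), topology.cbeta_proxy_index(j))
                         for i, j in ss_resids], dtype=np.int64).reshape(-1, 2)
    if mode == MODE_STATIC and native_coords is not None:
        ss_r0 = np.array([np.linalg.norm(native_coords[i] - native_coords[j])
                          for i, j in ss_pairs], dtype=float)
    else:
        ss_r0 = np.full(max(len(ss_pairs), 1), redox.dyn.r_bond, dtype=float)[:len(ss_pairs)]

    extra_restraints = extra_restraints or []
    extra_pairs = np.array([(r[0], r[1]) for r in extra_restraints],
                           dtype=np.int64).reshape(-1, 2)
    extra_k = np.array([r[2] for r in extra_restraints], dtype=float)
    extra_r0 = np.array([r[3] for r in extra_restraints], dtype=float)

    iu, ju = np.triu_indices(n, k=1)
    keep = excl[iu, ju] == 0
    ev_pairs = np.ascontiguousarray(
        np.stack([iu[keep], ju[keep]], axis=1).astype(np.int64))

    return CGSystem(
        n_beads=n, masses=np.full(n, BEAD_MASS),
        bonds=bonds_arr, bond_k=bond_k, bond_r0=bond_r0,
        contacts=contacts_arr, contact_r0=contact_r0, contact_eps=contact_eps,
        dihedrals=dih, dih_phi0=phi0, k_dih=go.k_dih,
        ev_pairs=ev_pairs, sigma_ev=go.sigma_ev, eps_ev=go.eps_ev,
        mode=mode, ss_pairs=ss_pairs, ss_pair_resids=ss_resids,
        ss_r0=ss_r0, k_static=redox.k_static,
        d_par=redox.dyn.as_array, t_par=redox.triplet.as_array,
        r_par=redox.restraint.as_array, cys_sc=cys_sc,
        extra_pairs=extra_pairs, extra_k=extra_k, extra_r0=extra_r0)


def _check_overlaps(coords: np.ndarray, limit: float = 0.1) -> None:
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    if d2[i, j] < limit * limit:
        raise OverlappingBeadsError(
            f"beads {i} and {j} overlap (r = {np.sqrt(d2[i, j]):.3f} Å < {limit} Å)")


def system_energy_forces(coords: np.ndarray, system: CGSystem):
    """Evaluate (energy, forces, per-pair SS energies) for a compiled system."""
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    _check_overlaps(coords)
    F = np.zeros_like(coords)
    ss_E = np.zeros(max(len(system.ss_pairs), 1))
    e_go, e_ss, e_tr = _kernels.compute_forces(
        np.ascontiguousarray(coords, dtype=float), F, *system.kernel_args(), ss_E)
    per_pair = {tuple(p): ss_E[m] for m, p in enumerate(system.ss_pair_resids)}
    return e_go + e_ss + e_tr, F, {"pairs": per_pair, "triplet": e_tr,
                                   "go": e_go, "ss": e_ss}


def go_energy_forces(coords: np.ndarray, topology: "ChainTopology",
                     go: GoParams | None = None):
    """Gō background energy and per-bead forces (no disulfide terms)."""
    go = go or GoParams()
    system = build_system(topology, go, RedoxModel(mode="none"))
    e, F, _ = system_energy_forces(coords, system)
    return e, F


def total_energy_forces(coords: np.ndarray, topology: "ChainTopology",
                        go: GoParams | None = None,
                        redox: RedoxModel | None = None,
                        native_coords: np.ndarray | None = None):
    """Total energy = Gō + mode-dependent SS terms.

    Returns (energy, forces, bookkeeping dict with per-pair SS energies,
    the triplet penalty, and the Gō/SS split).
    """
    go = go or GoParams()
    redox = redox or RedoxModel()
    system = build_system(topology, go, redox, native_coords=native_coords)
    return system_energy_forces(coords, system)


def minimize_energy(coords: np.ndarray, system: CGSystem,
                    maxiter: int = 1000, gtol: float = 1e-6) -> np.ndarray:
    """L-BFGS energy minimization on a compiled system; returns coordinates."""
    from scipy.optimize import minimize

    n = coords.shape[0]
    F = np.zeros_like(coords)
    ss_E = np.zeros(max(len(system.ss_pairs), 1))
    args = system.kernel_args()

    def fun(flat):
        x = flat.reshape(n, 3)
        e_go, e_ss, e_tr = _kernels.compute_forces(
            np.ascontiguousarray(x), F, *args, ss_E)
        return e_go + e_ss + e_tr, -F.ravel().copy()

    res = minimize(fun, coords.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14})
    return res.x.reshape(n, 3)
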