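"""Chain topologies: synthetic crosslinked toy folds and PDB-derived models.

A topology carries two interaction centers per residue — a backbone center
(Cα) and, where the residue has a side chain, a side center at the
side-chain heavy-atom centroid — plus backbone connectivity, native
contacts grouped by structural element, cysteine positions, designated
crosslinks and the two pulling anchors.

The synthetic generator emulates a small folded protein: helical and
sheet-like blocks laid out on a compact serpentine, relaxed under the Gō
background potential, with 2-4 cysteine crosslinks closed during
construction.  The stock RNase-A mimic reproduces the size (124 residues),
the four-crosslink nesting (Cys26-Cys84, Cys40-Cys95, Cys58-Cys110,
Cys65-Cys72) and the anchor convention (second and second-to-last
residues) of the real enzyme.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

BACKBONE = "backbone-center"
SIDECHAIN = "side-center"

#: default backbone virtual-bond length, Å
BB_BOND = 3.8
#: side-center attachment length, Å
SC_BOND = 1.8
#: Cβ-distance cutoff declaring a disulfide bond present, Å
SS_CUTOFF = 5.5
#: native-contact detection cutoffs, Å
BB_CONTACT_CUTOFF = 8.0
SC_CONTACT_CUTOFF = 6.0


class UnsatisfiableCrosslinkError(ValueError):
    """A requested crosslink could not be closed in any embedding."""


@dataclass
class Bead:
    """One interaction center: residue ordinal, kind, name and position (Å)."""

    index: int
    kind: str
    residue_name: str
    position: np.ndarray


@dataclass
class NativeContact:
    """Native contact between residues i < j at equilibrium distance r0."""

    i: int
    j: int
    r0: float
    element: str
    kind: str = "bb"   # 'bb' (backbone-backbone) or 'sc' (side-side)


@dataclass
class ChainTopology:
    n_residues: int
    beads: list
    backbone_bonds: list           # (res_i, res_j, r0)
    side_bonds: list               # (bead_i, bead_j, r0), bead indices
    native_contacts: list          # NativeContact
    native_dihedrals: list         # (b1, b2, b3, b4, phi0), bead indices
    cysteines: set
    crosslinks: list               # residue-ordinal pairs, native bonds
    anchors: tuple
    bb_index: np.ndarray           # residue -> backbone bead index
    sc_index: np.ndarray           # residue -> side bead index or -1
    cbeta: dict = field(default_factory=dict)   # residue -> Cβ coords (loaded structures)

    def __post_init__(self):
        for c in self.native_contacts:
            if abs(c.i - c.j) < 3:
                raise ValueError(f"native contact {c.i}-{c.j} violates |i-j| >= 3")
        cys = self.cysteines
        for i, j in self.crosslinks:
            if i not in cys or j not in cys:
                raise ValueError(f"crosslink ({i},{j}) is not between cysteines")
        if self.anchors[0] == self.anchors[1]:
            raise ValueError("anchors must be distinct")

    # -- bead-level views ---------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def native_coords(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    def bead_residues(self) -> np.ndarray:
        return np.array([b.index for b in self.beads], dtype=np.int64)

    def all_bonds(self):
        """Yield (bead_i, bead_j, r0) for backbone and side-attachment bonds."""
        for i, j, r0 in self.backbone_bonds:
            yield int(self.bb_index[i]), int(self.bb_index[j]), r0
        for bi, bj, r0 in self.side_bonds:
            yield bi, bj, r0

    def contact_bead_indices(self, c: NativeContact):
        if c.kind == "sc":
            return int(self.sc_index[c.i]), int(self.sc_index[c.j])
        return int(self.bb_index[c.i]), int(self.bb_index[c.j])

    def cbeta_proxy_index(self, res: int) -> int:
        """Bead index used for the Cβ-based bond criterion (side center,
        falling back on the backbone center for glycine-like residues)."""
        si = int(self.sc_index[res])
        return si if si >= 0 else int(self.bb_index[res])

    def cbeta_proxy_coords(self, res: int, coords: np.ndarray | None = None) -> np.ndarray:
        if coords is None and res in self.cbeta:
            return np.asarray(self.cbeta[res])
        x = coords if coords is not None else self.native_coords()
        return x[self.cbeta_proxy_index(res)]

    def anchor_bead_indices(self):
        return int(self.bb_index[self.anchors[0]]), int(self.bb_index[self.anchors[1]])


# ---------------------------------------------------------------------------
# toy-fold specification and generation
# ---------------------------------------------------------------------------

_BLOCK_KINDS = ("helix", "sheet", "loop")


@dataclass(frozen=True)
class ToyFoldSpec:
    """Layout of a synthetic fold: ordered (kind, length) blocks tiling the
    chain, crosslink pairs placed in loop or sheet blocks, and a seed."""

    n_residues: int
    blocks: tuple
    crosslinks: tuple = ()
    seed: int = 0
    anchors: tuple | None = None

    def __post_init__(self):
        total = 0
        for kind, length in self.blocks:
            if kind not in _BLOCK_KINDS:
                raise ValueError(f"unknown block kind {kind!r}")
            if length < 1:
                raise ValueError("block lengths must be >= 1")
            total += length
        if total != self.n_residues:
            raise ValueError(f"blocks tile {total} residues, expected {self.n_residues}")
        kinds = self.residue_block_kinds()
        for i, j in self.crosslinks:
            for r in (i, j):
                if not (0 <= r < self.n_residues):
                    raise ValueError(f"crosslink residue {r} outside chain")
                if kinds[r] == "helix":
                    raise ValueError(
                        f"crosslink residue {r} lies in a helix block; "
                        "crosslinks must sit in loop or sheet blocks")
            if abs(i - j) < 3:
                raise ValueError(f"crosslink ({i},{j}) too close in sequence")

    def residue_block_kinds(self):
        kinds = []
        for kind, length in self.blocks:
            kinds.extend([kind] * length)
        return kinds

    def residue_block_labels(self):
        labels, nh, nb, nl = [], 0, 0, 0
        for kind, length in self.blocks:
            if kind == "helix":
                nh += 1
                name = f"H{nh}"
            elif kind == "sheet":
                nb += 1
                name = f"B{nb}"
            else:
                nl += 1
                name = f"L{nl}"
            labels.extend([name] * length)
        return labels


def default_toy_spec(seed: int = 0) -> ToyFoldSpec:
    """A 40-residue helix + two-stranded-sheet fold with two crosslinks."""
    blocks = (("loop", 3), ("helix", 10), ("loop", 5), ("sheet", 7),
              ("loop", 3), ("sheet", 7), ("loop", 5))
    return ToyFoldSpec(n_residues=40, blocks=blocks,
                       crosslinks=((2, 37), (15, 26)), seed=seed)


def rnase_mimic_spec(seed: int = 0) -> ToyFoldSpec:
    """A 124-residue mimic of the RNase A architecture: three helices, seven
    sheet-like strands, and the four nested crosslinks at the published
    cysteine positions (0-based 25-83, 39-94, 57-109, 64-71).

    Element boundaries are nudged by 1-2 residues relative to the real
    protein so every cysteine sits in a loop or strand block.
    """
    blocks = (("loop", 2), ("helix", 11), ("loop", 13), ("helix", 7),
              ("loop", 9), ("sheet", 5), ("loop", 2), ("helix", 8),
              ("loop", 3), ("sheet", 3), ("loop", 8), ("sheet", 3),
              ("loop", 4), ("sheet", 8), ("loop", 10), ("sheet", 8),
              ("loop", 1), ("sheet", 6), ("loop", 4), ("sheet", 8),
              ("loop", 1))
    return ToyFoldSpec(n_residues=124, blocks=blocks,
                       crosslinks=((25, 83), (39, 94), (57, 109), (64, 71)),
                       seed=seed)


def _layout_backbone(spec: ToyFoldSpec, rng: np.random.Generator) -> np.ndarray:
    """Initial serpentine embedding: each helix/sheet block on its own row of
    a (y, z) grid, loops interpolated between rows."""
    n = spec.n_residues
    pos = np.zeros((n, 3))
    structured = [b for b in spec.blocks if b[0] != "loop"]
    wrap = max(1, int(np.ceil(np.sqrt(max(len(structured), 1)))))

    row = 0
    x = 0.0
    placed = np.zeros(n, dtype=bool)
    start = 0
    segments = []
    for kind, length in spec.blocks:
        segments.append((kind, start, length))
        start += length

    for kind, s0, length in segments:
        if kind == "loop":
            continue
        y = 6.0 * (row % wrap)
        z = 7.0 * (row // wrap)
        dirx = 1.0 if row % 2 == 0 else -1.0
        rise = 1.5 if kind == "helix" else 3.3
        theta = 0.0
        for m in range(length):
            xi = x + dirx * rise * (m + 1)
            if kind == "helix":
                pos[s0 + m] = (xi, y + 2.3 * np.cos(theta), z + 2.3 * np.sin(theta))
                theta += 1.75
            else:
                pos[s0 + m] = (xi, y, z + 0.6 * (-1.0) ** m)
            placed[s0 + m] = True
        x = x + dirx * rise * length
        row += 1

    # loops: straight interpolation between flanking placed residues
    for kind, s0, length in segments:
        if kind != "loop":
            continue
        prev = s0 - 1
        nxt = s0 + length
        if prev < 0 and nxt >= n:
            for m in range(length):
                pos[s0 + m] = (3.5 * m, 0.0, 0.0)
        elif prev < 0:
            d = np.array([-3.5, 0.0, 0.0])
            for m in range(length):
                pos[s0 + m] = pos[nxt] + d * (length - m)
        elif nxt >= n:
            d = np.array([3.5, 0.0, 0.0])
            for m in range(length):
                pos[s0 + m] = pos[prev] + d * (m + 1)
        else:
            a, b = pos[prev], pos[nxt]
            axis = b - a
            perp = np.cross(axis, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(axis, np.array([0.0, 1.0, 0.0]))
            perp = perp / max(np.linalg.norm(perp), 1e-9)
            for m in range(length):
                f = (m + 1) / (length + 1)
                bulge = 2.5 * np.sin(np.pi * f)
                pos[s0 + m] = a + axis * f + perp * bulge
        placed[s0:s0 + length] = True

    pos += rng.normal(scale=0.15, size=pos.shape)
    return pos


def _side_positions(bb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = bb.shape[0]
    sc = np.empty_like(bb)
    zhat = np.array([0.0, 0.0, 1.0])
    yhat = np.array([0.0, 1.0, 0.0])
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        t = bb[hi] - bb[lo]
        t = t / max(np.linalg.norm(t), 1e-9)
        ref = zhat if abs(t @ zhat) < 0.9 else yhat
        u = np.cross(t, ref)
        u = u / max(np.linalg.norm(u), 1e-9)
        sc[i] = bb[i] + SC_BOND * u
    sc += rng.normal(scale=0.1, size=sc.shape)
    return sc


def _dihedral_angle(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-9:
        return 0.0
    sinp = np.dot(np.cross(n1, n2), b2) / b2n
    cosp = np.dot(n1, n2)
    return float(np.arctan2(sinp, cosp))


def _assemble(spec_like, coords: np.ndarray, residue_names: list,
              crosslinks, anchors, labels=None, cysteines=None) -> ChainTopology:
    """Build a ChainTopology from bead coordinates laid out as
    [bb_0..bb_{n-1}, sc_0..sc_{n-1}] (every residue with a side bead)."""
    n = coords.shape[0] // 2
    bb, sc = coords[:n], coords[n:]
    beads = []
    bb_index = np.arange(n, dtype=np.int64)
    sc_index = np.arange(n, 2 * n, dtype=np.int64)
    for i in range(n):
        beads.append(Bead(i, BACKBONE, residue_names[i], bb[i].copy()))
    for i in range(n):
        beads.append(Bead(i, SIDECHAIN, residue_names[i], sc[i].copy()))

    backbone_bonds = [(i, i + 1, BB_BOND) for i in range(n - 1)]
    side_bonds = []
    for i in range(n):
        side_bonds.append((int(bb_index[i]), int(sc_index[i]), SC_BOND))
        nb = i + 1 if i + 1 < n else i - 1
        side_bonds.append((int(bb_index[nb]), int(sc_index[i]),
                           float(np.sqrt(SC_BOND ** 2 + BB_BOND ** 2))))

    labels = labels or ["T"] * n
    xl = {tuple(sorted(p)) for p in crosslinks}
    contacts = []
    for i in range(n):
        for j in range(i + 3, n):
            d = float(np.linalg.norm(bb[i] - bb[j]))
            if d < BB_CONTACT_CUTOFF:
                li, lj = labels[i], labels[j]
                if li == lj and not li.startswith("L") and li != "T":
                    el = li
                elif li.startswith("B") and lj.startswith("B") and "-" not in li + lj:
                    el = f"{min(li, lj)}-{max(li, lj)}"
                else:
                    el = "T"
                contacts.append(NativeContact(i, j, d, el, "bb"))
            ds = float(np.linalg.norm(sc[i] - sc[j]))
            if ds < SC_CONTACT_CUTOFF or (i, j) in xl:
                el = "SS" if (i, j) in xl else "T"
                contacts.append(NativeContact(i, j, ds, el, "sc"))

    dihedrals = []
    for i in range(n - 3):
        phi0 = _dihedral_angle(bb[i], bb[i + 1], bb[i + 2], bb[i + 3])
        dihedrals.append((int(bb_index[i]), int(bb_index[i + 1]),
                          int(bb_index[i + 2]), int(bb_index[i + 3]), phi0))

    cys = cysteines if cysteines is not None else {r for p in crosslinks for r in p}
    return ChainTopology(
        n_residues=n, beads=beads, backbone_bonds=backbone_bonds,
        side_bonds=side_bonds, native_contacts=contacts,
        native_dihedrals=dihedrals, cysteines=set(cys),
        crosslinks=[tuple(sorted(p)) for p in crosslinks], anchors=anchors,
        bb_index=bb_index, sc_index=sc_index)


def generate_toy_fold(spec: ToyFoldSpec):
    """Build a self-avoiding folded conformation realizing ``spec``.

    Returns (topology, native coordinates).  The construction is fully
    deterministic for a given spec + seed: serpentine layout, staged
    minimization closing the crosslinks, native-contact/dihedral harvesting,
    then a final relaxation under the resulting Gō potential so the returned
    conformation is a local energy minimum.
    """
    from .potentials import GoParams, RedoxModel, build_system, minimize_energy

    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    bb = _layout_backbone(spec, rng)
    sc = _side_positions(bb, rng)
    coords = np.vstack([bb, sc])

    cys = sorted({r for p in spec.crosslinks for r in p})
    names = ["CYS" if i in cys else "ALA" for i in range(n)]
    anchors = spec.anchors if spec.anchors is not None else (1, n - 2)
    if n < 3:
        raise ValueError("need at least 3 residues")
    labels = spec.residue_block_labels()

    # stage 1: bonds + excluded volume, crosslinks pulled shut by ramped
    # harmonic scaffolds on the side centers
    proto = _assemble(spec, coords, names, [], anchors, labels=labels,
                      cysteines=set(cys))
    proto.native_contacts = []
    proto.native_dihedrals = []
    go = GoParams()
    for k_restr in (1.0, 10.0, 50.0):
        restraints = [(int(proto.sc_index[i]), int(proto.sc_index[j]), k_restr, 4.0)
                      for i, j in spec.crosslinks]
        system = build_system(proto, go, RedoxModel(mode="none"),
                              extra_restraints=restraints)
        coords = minimize_energy(coords, system, maxiter=600, gtol=1e-5)

    for i, j in spec.crosslinks:
        d = np.linalg.norm(coords[proto.sc_index[i]] - coords[proto.sc_index[j]])
        if d >= SS_CUTOFF:
            raise UnsatisfiableCrosslinkError(
                f"crosslink ({i},{j}) could not be closed: side-center distance "
                f"{d:.2f} Å >= {SS_CUTOFF} Å after construction")

    # stage 2: harvest native contacts + dihedrals, final relaxation
    topo = _assemble(spec, coords, names, spec.crosslinks, anchors,
                     labels=labels, cysteines=set(cys))
    system = build_system(topo, go, RedoxModel(mode="none"))
    coords = minimize_energy(coords, system, maxiter=6000, gtol=1e-4)

    for i, j in spec.crosslinks:
        d = np.linalg.norm(coords[topo.sc_index[i]] - coords[topo.sc_index[j]])
        if d >= SS_CUTOFF:
            raise UnsatisfiableCrosslinkError(
                f"crosslink ({i},{j}) drifted open during relaxation ({d:.2f} Å)")
    _check_self_avoiding(topo, coords)

    for b, x in zip(topo.beads, coords):
        b.position = x.copy()
    return topo, coords


def _check_self_avoiding(topo: ChainTopology, coords: np.ndarray,
                         min_dist: float = 2.0) -> None:
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    resid = topo.bead_residues()
    near = np.abs(resid[:, None] - resid[None, :]) <= 1
    d[near] = np.inf
    np.fill_diagonal(d, np.inf)
    if d.min() < min_dist:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(
            f"generated fold is not self-avoiding: beads {i},{j} at {d[i, j]:.2f} Å")


# ---------------------------------------------------------------------------
# real structures
# ---------------------------------------------------------------------------

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def load_structure(pdb_text: str):
    """Derive a topology from single-chain PDB text.

    One backbone bead per residue at Cα; one side-center bead at the
    side-chain heavy-atom centroid (Cβ coordinates are retained separately
    for the bond-fraction criterion).  Altloc duplicates are reduced to the
    highest-occupancy copy.  Residues without a Cα are skipped with a
    warning; an empty chain is an error.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb.get_structure(model=1, altloc="occupancy",
                              extra_fields=["occupancy"])
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError("no protein atoms in PDB input")
    # group atoms of each residue together regardless of record order
    atoms = atoms[np.argsort(atoms.res_id, kind="stable")]
    chains = np.unique(atoms.chain_id)
    if len(chains) > 1:
        raise ValueError(f"expected a single chain, found {list(chains)}")

    bb_pos, sc_pos, names, cbeta = [], [], [], {}
    ordinal = 0
    for res_atoms in struc.residue_iter(atoms):
        ca = res_atoms[res_atoms.atom_name == "CA"]
        resname = res_atoms.res_name[0]
        if ca.array_length() == 0:
            warnings.warn(f"residue {resname} {res_atoms.res_id[0]} has no CA; skipped")
            continue
        side = res_atoms[
            ~np.isin(res_atoms.atom_name, list(_BACKBONE_ATOMS))
            & (res_atoms.element != "H")]
        bb_pos.append(ca.coord[0])
        sc_pos.append(side.coord.mean(axis=0) if side.array_length() > 0 else None)
        cb = res_atoms[res_atoms.atom_name == "CB"]
        if cb.array_length() > 0:
            cbeta[ordinal] = np.array(cb.coord[0], dtype=float)
        names.append(resname)
        ordinal += 1

    n = len(bb_pos)
    if n == 0:
        raise ValueError("no residues with CA found")
    bb = np.array(bb_pos, dtype=float)
    # glycine-like residues get a pseudo side center 0.9 Å off the backbone
    # (a zero-length side bond would collide with the overlap guard)
    zhat = np.array([0.0, 0.0, 1.0])
    yhat = np.array([0.0, 1.0, 0.0])
    sc = np.empty_like(bb)
    for i, s in enumerate(sc_pos):
        if s is not None:
            sc[i] = s
            continue
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        t = bb[hi] - bb[lo]
        t = t / max(np.linalg.norm(t), 1e-9)
        ref = zhat if abs(t @ zhat) < 0.9 else yhat
        u = np.cross(t, ref)
        sc[i] = bb[i] + 0.9 * u / max(np.linalg.norm(u), 1e-9)

    if n < 2:
        raise ValueError("need at least 2 residues with CA")
    coords = np.vstack([bb, sc])
    cys = {i for i, nm in enumerate(names) if nm == "CYS"}
    anchors = (1, n - 2) if n >= 4 else (0, n - 1)
    topo = _assemble(None, coords, names, [], anchors, cysteines=cys)
    topo.cbeta = {i: (cbeta[i] if i in cbeta else bb[i]) for i in range(n)}
    # measured backbone-bond lengths
    topo.backbone_bonds = [(i, i + 1, float(np.linalg.norm(bb[i + 1] - bb[i])))
                           for i in range(n - 1)]
    topo.side_bonds = []
    for i in range(n):
        r1 = float(np.linalg.norm(sc[i] - bb[i]))
        topo.side_bonds.append((int(topo.bb_index[i]), int(topo.sc_index[i]),
                                max(r1, 0.5)))
        nb = i + 1 if i + 1 < n else i - 1
        r2 = float(np.linalg.norm(sc[i] - bb[nb]))
        topo.side_bonds.append((int(topo.bb_index[nb]), int(topo.sc_index[i]),
                                max(r2, 0.5)))
    topo.crosslinks = detect_disulfides(topo, coords)
    return topo, coords


def detect_disulfides(topology: ChainTopology, coords: np.ndarray | None = None,
                      cutoff: float = SS_CUTOFF):
    """Cysteine pairs with Cβ (or side-center fallback) distance < cutoff.

    Greedy matching by ascending distance: each cysteine gets at most one
    partner, mirroring the triplet repulsion that forbids triple bonds.
    """
    cys = sorted(topology.cysteines)
    cand = []
    for a in range(len(cys)):
        for b in range(a + 1, len(cys)):
            pi = topology.cbeta_proxy_coords(cys[a], coords)
            pj = topology.cbeta_proxy_coords(cys[b], coords)
            d = float(np.linalg.norm(pi - pj))
            if d < cutoff:
                cand.append((d, cys[a], cys[b]))
    cand.sort()
    used, pairs = set(), []
    for d, i, j in cand:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append((i, j))
    return sorted(pairs)


def max_extension_bound(topology: ChainTopology,
                        crosslink_state=None,
                        d_ss: float = 4.0) -> float:
    """Upper bound on anchor separation with inextensible links (Å).

    Shortest anchor-to-anchor path in the graph whose edges are backbone
    bonds (weight = equilibrium length) and intact crosslinks
    (weight = the bonded-well equilibrium distance ``d_ss``).
    """
    intact = (topology.crosslinks if crosslink_state is None
              else [tuple(sorted(p)) for p in crosslink_state])
    g = nx.Graph()
    g.add_nodes_from(range(topology.n_residues))
    for i, j, r0 in topology.backbone_bonds:
        g.add_edge(i, j, weight=r0)
    for i, j in intact:
        w = min(d_ss, g.get_edge_data(i, j, {"weight": np.inf})["weight"])
        g.add_edge(i, j, weight=w)
    a, b = topology.anchors
    try:
        return float(nx.dijkstra_path_length(g, a, b))
    except nx.NetworkXNoPath as err:
        raise ValueError("anchor residues are not connected") from err


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_pdb(topology: ChainTopology, coords: np.ndarray, path) -> None:
    """Write a single-model PDB: CA for backbone beads, CB pseudo-atoms for
    side centers."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_beads = topology.n_beads
    # interleave beads per residue (CA then CB) for conventional PDB order
    order = sorted(range(n_beads),
                   key=lambda k: (topology.beads[k].index,
                                  topology.beads[k].kind != BACKBONE))
    beads = [topology.beads[k] for k in order]
    arr = struc.AtomArray(n_beads)
    arr.coord = np.asarray(coords, dtype=np.float32)[order]
    arr.chain_id = np.full(n_beads, "A")
    arr.res_id = np.array([b.index + 1 for b in beads])
    arr.res_name = np.array([b.residue_name for b in beads])
    arr.atom_name = np.array(
        ["CA" if b.kind == BACKBONE else "CB" for b in beads])
    arr.element = np.full(n_beads, "C")
    arr.hetero = np.zeros(n_beads, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_topology(topology: ChainTopology, prefix) -> None:
    """Write the topology as a TSV bundle: beads / bonds / contacts /
    crosslinks (+ cysteines, anchors) under ``<prefix>_*.tsv``."""
    import pandas as pd

    pd.DataFrame(
        [(b.index, b.kind, b.residue_name, *b.position) for b in topology.beads],
        columns=["residue", "kind", "res_name", "x", "y", "z"],
    ).to_csv(f"{prefix}_beads.tsv", sep="\t", index=False)
    rows = [(bi, bj, r0, "backbone") for bi, bj, r0 in
            ((int(topology.bb_index[i]), int(topology.bb_index[j]), r0)
             for i, j, r0 in topology.backbone_bonds)]
    rows += [(bi, bj, r0, "side") for bi, bj, r0 in topology.side_bonds]
    pd.DataFrame(rows, columns=["bead_i", "bead_j", "r0", "kind"]).to_csv(
        f"{prefix}_bonds.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(c.i, c.j, c.r0, c.element, c.kind) for c in topology.native_contacts],
        columns=["res_i", "res_j", "r0", "element", "kind"],
    ).to_csv(f"{prefix}_contacts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(d[0], d[1], d[2], d[3], d[4]) for d in topology.native_dihedrals],
        columns=["b1", "b2", "b3", "b4", "phi0"],
    ).to_csv(f"{prefix}_dihedrals.tsv", sep="\t", index=False)
    with open(f"{prefix}_crosslinks.tsv", "w") as fh:
        fh.write(f"# cysteines\t{','.join(map(str, sorted(topology.cysteines)))}\n")
        fh.write(f"# anchors\t{topology.anchors[0]},{topology.anchors[1]}\n")
        fh.write("res_i\tres_j\n")
        for i, j in topology.crosslinks:
            fh.write(f"{i}\t{j}\n")
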