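"""Analysis of steered-MD force logs and trajectories.

All per-extension profiles use 1 Å bins; each bin pools every observation
(from every trajectory) that falls in it, and reports the pooled mean and
the standard error of the mean (sample standard deviation / sqrt(n)).
Unpopulated bins are flagged absent (n = 0, NaN mean), never zero.

Structure comparison uses exact rigid-body superposition (Kabsch, rotations
only — reflections disallowed); the representative conformer of an
ensemble is the member minimizing the sum of pairwise RMSDs to all others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import BondEvent, Trajectory
from .potentials import RestraintParams
from .topology import SS_CUTOFF, ChainTopology
from .units import KCAL_PER_MOL_ANG_TO_PN


@dataclass
class ForceExtensionProfile:
    """Mean force (pN) vs extension in fixed-width bins."""

    bin_edges: np.ndarray          # length n_bins + 1, Å
    mean: np.ndarray               # NaN where n == 0
    sem: np.ndarray
    n: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def populated(self) -> np.ndarray:
        return self.n > 0


@dataclass
class FractionProfile:
    """Per-bin fraction in [0, 1] for each labelled quantity."""

    bin_edges: np.ndarray
    fractions: dict                # label -> array (NaN where n == 0)
    n: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PeakSet:
    peaks: list                    # (extension Å, force pN, 'maximum'|'minimum')

    def maxima(self):
        return [p for p in self.peaks if p[2] == "maximum"]

    def minima(self):
        return [p for p in self.peaks if p[2] == "minimum"]


@dataclass
class RepresentativeResult:
    frame_id: int
    window: tuple
    rmsd_sums: dict                # frame id -> sum of pairwise RMSDs


def _gather(trajectories, attr="force_pN"):
    ext = np.concatenate([t.extension for t in trajectories])
    val = np.concatenate([getattr(t, attr) for t in trajectories])
    return ext, val


def _bin_edges(ext: np.ndarray, bin_width: float) -> np.ndarray:
    lo = np.floor(ext.min() / bin_width) * bin_width
    hi = np.floor(ext.max() / bin_width) * bin_width + bin_width
    return np.arange(lo, hi + 0.5 * bin_width, bin_width)


def bin_force_extension(trajectories, bin_width: float = 1.0,
                        forces=None) -> ForceExtensionProfile:
    """Pooled force-extension profile over one or more trajectories.

    ``forces`` optionally substitutes a corrected force series per
    trajectory (same frame layout), e.g. after break-force subtraction.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    ext = np.concatenate([t.extension for t in trajectories])
    if forces is not None:
        val = np.concatenate([np.asarray(f, dtype=float) for f in forces])
    else:
        val = np.concatenate([t.force_pN for t in trajectories])
    if not (np.all(np.isfinite(ext)) and np.all(np.isfinite(val))):
        raise ValueError("non-finite extension or force values")
    edges = _bin_edges(ext, bin_width)
    nb = len(edges) - 1
    idx = np.clip(((ext - edges[0]) / bin_width).astype(int), 0, nb - 1)
    n = np.bincount(idx, minlength=nb).astype(int)
    s = np.bincount(idx, weights=val, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        ss = np.bincount(idx, weights=val * val, minlength=nb)
        var = np.where(n > 1, (ss - n * mean ** 2) / np.maximum(n - 1, 1), 0.0)
        var = np.clip(var, 0.0, None)
        sem = np.where(n > 0, np.sqrt(var) / np.sqrt(np.maximum(n, 1)), np.nan)
    return ForceExtensionProfile(bin_edges=edges, mean=mean, sem=sem, n=n)


def subtract_break_force(force_pN: np.ndarray, steps: np.ndarray,
                         events, mode: str,
                         restraint: RestraintParams | None = None) -> np.ndarray:
    """Subtract the constant restraint-tail force after each final break.

    Once a restrained pair has permanently entered the linear tail (its
    final break event), its constant tail force — 2 k (r3 - r2), 555.8 pN
    at defaults — rides on every subsequent spring-force reading and is
    removed here.  Only meaningful for restraint-mode runs.
    """
    if mode != "restraint":
        raise ValueError("break-force subtraction applies to restraint mode only")
    p = restraint or RestraintParams()
    f_const = p.tail_force * KCAL_PER_MOL_ANG_TO_PN
    out = np.array(force_pN, dtype=float)
    final_break = {}
    for e in events:
        if e.kind == "break":
            final_break[e.pair] = e.step
        elif e.kind == "form" and e.pair in final_break:
            del final_break[e.pair]   # reformation cancels a prior break
    for step0 in final_break.values():
        out[steps > step0] -= f_const
    return out


def bond_fraction_vs_extension(trajectories, pairs=None,
                               cutoff: float = SS_CUTOFF,
                               bin_width: float = 1.0) -> FractionProfile:
    """Fraction of observations with pair distance < cutoff, per 1 Å bin.

    Covers native and non-native cysteine pairs alike; ``pairs`` defaults
    to every pair logged in the trajectories.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    all_pairs = trajectories[0].ss_pairs
    pairs = [tuple(p) for p in (pairs if pairs is not None else all_pairs)]
    for p in pairs:
        if p not in all_pairs:
            raise ValueError(f"pair {p} not logged in trajectories")
    ext = np.concatenate([t.extension for t in trajectories])
    edges = _bin_edges(ext, bin_width)
    nb = len(edges) - 1
    idx = np.clip(((ext - edges[0]) / bin_width).astype(int), 0, nb - 1)
    n = np.bincount(idx, minlength=nb).astype(int)
    fractions = {}
    for p in pairs:
        m = all_pairs.index(p)
        flag = np.concatenate([t.ss_dist[:, m] < cutoff for t in trajectories])
        hits = np.bincount(idx, weights=flag.astype(float), minlength=nb)
        with np.errstate(invalid="ignore"):
            fractions[p] = np.where(n > 0, hits / np.maximum(n, 1), np.nan)
    return FractionProfile(bin_edges=edges, fractions=fractions, n=n)


def contact_fraction_by_element(trajectories, topology: ChainTopology,
                                bin_width: float = 1.0,
                                tolerance: float = 1.2) -> FractionProfile:
    """Per-element fraction of native contacts within ``tolerance`` × native
    distance, per extension bin (secondary-structure proxy)."""
    import warnings as _warnings

    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    elements = sorted({c.element for c in topology.native_contacts})
    by_el = {el: [] for el in elements}
    for c in topology.native_contacts:
        bi, bj = topology.contact_bead_indices(c)
        by_el[c.element].append((bi, bj, c.r0))
    for el in list(by_el):
        if not by_el[el]:
            _warnings.warn(f"element {el} has no native contacts; excluded")
            del by_el[el]

    ext = np.concatenate([t.extension for t in trajectories])
    edges = _bin_edges(ext, bin_width)
    nb = len(edges) - 1
    idx_all = np.clip(((ext - edges[0]) / bin_width).astype(int), 0, nb - 1)
    n = np.bincount(idx_all, minlength=nb).astype(int)

    fractions = {}
    for el, specs in by_el.items():
        ii = np.array([s[0] for s in specs])
        jj = np.array([s[1] for s in specs])
        r0 = np.array([s[2] for s in specs])
        hits = np.zeros(nb)
        tot = np.zeros(nb)
        off = 0
        for t in trajectories:
            d = np.linalg.norm(t.xs[:, ii, :].astype(float)
                               - t.xs[:, jj, :].astype(float), axis=-1)
            formed = (d < tolerance * r0).mean(axis=1)
            idx = idx_all[off:off + t.n_frames]
            hits += np.bincount(idx, weights=formed, minlength=nb)
            tot += np.bincount(idx, minlength=nb)
            off += t.n_frames
        with np.errstate(invalid="ignore"):
            fractions[el] = np.where(tot > 0, hits / np.maximum(tot, 1), np.nan)
    return FractionProfile(bin_edges=edges, fractions=fractions, n=n)


def detect_peaks(profile: ForceExtensionProfile, smooth_window: int = 5,
                 prominence: float | None = None) -> PeakSet:
    """Moving-average smoothing followed by a prominence-thresholded local
    extremum scan.  Default prominence: 2 × median SEM of populated bins."""
    from scipy.signal import find_peaks

    mask = profile.populated
    if mask.sum() == 0:
        raise ValueError("profile has no populated bins")
    x = profile.centers[mask]
    y = profile.mean[mask]
    if prominence is None:
        med_sem = np.nanmedian(profile.sem[mask])
        prominence = 2.0 * (med_sem if np.isfinite(med_sem) else 0.0)
    w = max(1, int(smooth_window))
    kernel = np.ones(w) / w
    ypad = np.concatenate([np.full(w // 2, y[0]), y, np.full(w - 1 - w // 2, y[-1])])
    ys = np.convolve(ypad, kernel, mode="valid")
    imax, _ = find_peaks(ys, prominence=prominence)
    peaks = []
    prev = None
    for k in imax:
        if prev is not None:
            interior = np.arange(prev + 1, k)
            if len(interior):
                kmin = interior[np.argmin(ys[interior])]
                peaks.append((float(x[kmin]), float(ys[kmin]), "minimum"))
        peaks.append((float(x[k]), float(ys[k]), "maximum"))
        prev = k
    return PeakSet(peaks=peaks)


# ---------------------------------------------------------------------------
# superposition and structural descriptors
# ---------------------------------------------------------------------------

def kabsch_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimum RMSD over rigid rotation + translation (reflections
    disallowed), via the SVD of the covariance matrix."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"size mismatch: {X.shape} vs {Y.shape}")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Yc - Xc @ R.T
    return float(np.sqrt((diff ** 2).sum() / X.shape[0]))


def superpose(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Return X rigidly superposed onto Y (rotation + translation)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return Xc @ R.T + Y.mean(axis=0)


def select_representative(coords_list, frame_ids=None,
                          window: tuple | None = None) -> RepresentativeResult:
    """Representative conformer: argmin of the sum of pairwise RMSDs
    (exact all-pairs table); ties broken by lowest frame id."""
    coords_list = [np.asarray(c, dtype=float) for c in coords_list]
    if not coords_list:
        raise ValueError("empty ensemble")
    ids = list(frame_ids) if frame_ids is not None else list(range(len(coords_list)))
    m = len(coords_list)
    table = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            table[a, b] = table[b, a] = kabsch_rmsd(coords_list[a], coords_list[b])
    sums = table.sum(axis=1)
    order = sorted(range(m), key=lambda a: (sums[a], ids[a]))
    best = order[0]
    return RepresentativeResult(
        frame_id=ids[best], window=window if window is not None else (np.nan, np.nan),
        rmsd_sums={ids[a]: float(sums[a]) for a in range(m)})


def representative_at(trajectories, target_extension: float,
                      half_width: float = 1.0,
                      bead_subset: np.ndarray | None = None) -> RepresentativeResult:
    """Representative conformer of the ensemble within ±half_width of the
    target extension (typically a force minimum), pooled over trajectories."""
    coords, ids = [], []
    fid = 0
    for t in trajectories:
        sel = np.abs(t.extension - target_extension) <= half_width
        for k in np.nonzero(sel)[0]:
            x = t.xs[k].astype(float)
            coords.append(x[bead_subset] if bead_subset is not None else x)
            ids.append(fid + k)
        fid += t.n_frames
    if not coords:
        raise ValueError(
            f"no frames within ±{half_width} Å of extension {target_extension} Å")
    res = select_representative(coords, ids)
    res.window = (target_extension - half_width, target_extension + half_width)
    return res


def rg_rgmax_rmsf(xs: np.ndarray, reference: np.ndarray | None = None):
    """Per-frame radius of gyration and maximum bead distance from the
    geometric center; per-bead RMSF about the mean structure (computed from
    the second half of frames, after superposition).

    Returns (rg, rgmax, rmsf)."""
    xs = np.asarray(xs, dtype=float)
    if xs.ndim != 3:
        raise ValueError("expected (n_frames, n_beads, 3) array")
    if xs.shape[0] < 2:
        raise ValueError("RMSF undefined for a single frame")
    center = xs.mean(axis=1, keepdims=True)
    dev = xs - center
    rg = np.sqrt((dev ** 2).sum(axis=-1).mean(axis=1))
    rgmax = np.sqrt((dev ** 2).sum(axis=-1)).max(axis=1)

    half = xs[xs.shape[0] // 2:]
    ref = np.asarray(reference, dtype=float) if reference is not None else half[0]
    aligned = np.array([superpose(f, ref) for f in half])
    mean_structure = aligned.mean(axis=0)
    aligned = np.array([superpose(f, mean_structure) for f in half])
    mean_structure = aligned.mean(axis=0)
    rmsf = np.sqrt(((aligned - mean_structure) ** 2).sum(axis=-1).mean(axis=0))
    return rg, rgmax, rmsf


# ---------------------------------------------------------------------------
# bond-event ordering
# ---------------------------------------------------------------------------

UNBROKEN = "unbroken"


def final_break_extensions(events, pairs) -> dict:
    """Final break extension per pair (reformation voids earlier breaks);
    pairs never (finally) broken map to None."""
    out = {tuple(p): None for p in pairs}
    for e in events:
        p = tuple(e.pair)
        if p not in out:
            continue
        if e.kind == "break":
            out[p] = e.extension
        elif e.kind == "form":
            out[p] = None
    return out


def breaking_order(events_per_trajectory, pairs):
    """Consensus breaking order over an ensemble.

    Per trajectory, pairs are ranked by their final break extension
    (unbroken pairs rank last); the consensus orders pairs by median rank,
    ties by median break extension.  Returns a list of
    (pair, median_rank, vote_counts, median_extension_or_None) in consensus
    order.
    """
    pairs = [tuple(p) for p in pairs]
    ranks = {p: [] for p in pairs}
    exts = {p: [] for p in pairs}
    for events in events_per_trajectory:
        fb = final_break_extensions(events, pairs)
        broken = sorted((e, p) for p, e in fb.items() if e is not None)
        order = {p: r for r, (e, p) in enumerate(broken)}
        unbroken_rank = len(pairs) - 1 + 0.5   # sorts after every broken rank
        for p in pairs:
            if fb[p] is None:
                ranks[p].append(unbroken_rank)
                exts[p].append(np.inf)
            else:
                ranks[p].append(order[p])
                exts[p].append(fb[p])
    result = []
    for p in pairs:
        med_rank = float(np.median(ranks[p]))
        med_ext = float(np.median(exts[p]))
        votes = {}
        for r in ranks[p]:
            key = UNBROKEN if r == len(pairs) - 0.5 else int(r)
            votes[key] = votes.get(key, 0) + 1
        result.append((p, med_rank, votes, None if not np.isfinite(med_ext) else med_ext))
    result.sort(key=lambda t: (t[1], np.inf if t[3] is None else t[3]))
    return result


# ---------------------------------------------------------------------------
# profile output
# ---------------------------------------------------------------------------

def write_profile(profile: ForceExtensionProfile, path, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("ext_center_A\tmean_force_pN\tsem_pN\tn\n")
        for c, m, s, n in zip(profile.centers, profile.mean, profile.sem, profile.n):
            if n == 0:
                continue
            fh.write(f"{c:.2f}\t{m:.4f}\t{s:.4f}\t{n}\n")


def write_fractions(profile: FractionProfile, path, header_extra: str = "") -> None:
    labels = sorted(profile.fractions, key=str)
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("ext_center_A\tn\t" + "\t".join(map(str, labels)) + "\n")
        for k, c in enumerate(profile.centers):
            if profile.n[k] == 0:
                continue
            vals = "\t".join(f"{profile.fractions[l][k]:.4f}" for l in labels)
            fh.write(f"{c:.2f}\t{profile.n[k]}\t{vals}\n")
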