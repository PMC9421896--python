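"""Profiles, corrections, peak detection, superposition, and event
ordering — each checked against small closed-form or brute-force oracles."""

import numpy as np
import pytest

from ssmech.analysis import (bin_force_extension, bond_fraction_vs_extension,
                             breaking_order, contact_fraction_by_element,
                             detect_peaks, final_break_extensions, kabsch_rmsd,
                             rg_rgmax_rmsf, select_representative,
                             subtract_break_force, superpose)
from ssmech.dynamics import BondEvent


class FakeTraj:
    """Minimal stand-in exposing the arrays the profile functions read."""

    def __init__(self, extension, force, ss_pairs=None, ss_dist=None, xs=None):
        self.extension = np.asarray(extension, dtype=float)
        self.force_pN = np.asarray(force, dtype=float)
        self.ss_pairs = ss_pairs or []
        self.ss_dist = ss_dist if ss_dist is not None else np.zeros((len(self.extension), 0))
        self.xs = xs
        self.n_frames = len(self.extension)


class TestBinForceExtension:
    def test_constant_force_single_trajectory(self):
        t = FakeTraj(np.linspace(0, 9.9, 100), np.full(100, 42.0))
        prof = bin_force_extension([t])
        assert np.allclose(prof.mean[prof.populated], 42.0)
        assert np.allclose(prof.sem[prof.populated], 0.0)

    def test_two_constant_trajectories_pooled_sem(self):
        # two observations per bin with values f1, f2:
        # mean = (f1+f2)/2, SEM = sd/sqrt(2) = |f1-f2|/2
        ext = np.arange(5) + 0.5
        t1 = FakeTraj(ext, np.full(5, 10.0))
        t2 = FakeTraj(ext, np.full(5, 16.0))
        prof = bin_force_extension([t1, t2])
        pop = prof.populated
        assert np.allclose(prof.mean[pop], 13.0)
        assert np.allclose(prof.sem[pop], 3.0)
        assert prof.n[pop].sum() == 10

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        ext = rng.uniform(0, 30, 500)
        force = rng.normal(300, 40, 500)
        perm = rng.permutation(500)
        p1 = bin_force_extension([FakeTraj(ext, force)])
        p2 = bin_force_extension([FakeTraj(ext[perm], force[perm])])
        assert np.allclose(p1.mean[p1.populated], p2.mean[p2.populated])
        assert np.allclose(p1.sem[p1.populated], p2.sem[p2.populated])

    def test_bin_count_conservation(self):
        rng = np.random.default_rng(6)
        ts = [FakeTraj(rng.uniform(0, 50, n), rng.normal(size=n))
              for n in (100, 57, 211)]
        prof = bin_force_extension(ts)
        assert prof.n.sum() == 100 + 57 + 211

    def test_unpopulated_bins_flagged_absent(self):
        t = FakeTraj([0.5, 10.5], [1.0, 2.0])
        prof = bin_force_extension([t])
        gap = (prof.n == 0)
        assert gap.any()
        assert np.all(np.isnan(prof.mean[gap]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_force_extension([])


class TestSubtractBreakForce:
    steps = np.arange(0, 1000, 100)
    force = np.full(10, 800.0)

    def test_no_events_unchanged(self):
        out = subtract_break_force(self.force, self.steps, [], "restraint")
        assert np.array_equal(out, self.force)

    def test_single_break_subtracts_tail_force(self):
        ev = [BondEvent((0, 5), "break", 450, 20.0)]
        out = subtract_break_force(self.force, self.steps, ev, "restraint")
        assert np.allclose(out[:5], 800.0)
        assert np.allclose(out[5:], 800.0 - 555.8, atol=0.1)

    def test_two_breaks_stack(self):
        ev = [BondEvent((0, 5), "break", 250, 10.0),
              BondEvent((1, 6), "break", 650, 30.0)]
        out = subtract_break_force(self.force, self.steps, ev, "restraint")
        assert np.allclose(out[:3], 800.0)
        assert np.allclose(out[3:7], 800.0 - 555.8, atol=0.1)
        assert np.allclose(out[7:], 800.0 - 2 * 555.8, atol=0.1)

    def test_reformation_cancels_break(self):
        ev = [BondEvent((0, 5), "break", 250, 10.0),
              BondEvent((0, 5), "form", 450, 12.0)]
        out = subtract_break_force(self.force, self.steps, ev, "restraint")
        assert np.array_equal(out, self.force)

    def test_rejected_outside_restraint_mode(self):
        with pytest.raises(ValueError, match="restraint"):
            subtract_break_force(self.force, self.steps, [], "dynamic")


class TestBondFraction:
    def _traj(self, dists):
        n = len(dists)
        return FakeTraj(np.linspace(0.5, 0.9, n), np.zeros(n),
                        ss_pairs=[(2, 5)], ss_dist=np.asarray(dists)[:, None])

    def test_all_bonded(self):
        prof = bond_fraction_vs_extension([self._traj([4.0] * 10)])
        assert np.allclose(prof.fractions[(2, 5)][prof.n > 0], 1.0)

    def test_half_bonded(self):
        prof = bond_fraction_vs_extension([self._traj([4.0] * 5 + [7.0] * 5)])
        assert prof.fractions[(2, 5)][prof.n > 0][0] == pytest.approx(0.5)

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            bond_fraction_vs_extension([self._traj([4.0])], pairs=[(1, 9)])


class TestDetectPeaks:
    def _profile(self, values):
        n = len(values)
        ext = np.repeat(np.arange(n) + 0.5, 3)
        force = np.repeat(np.asarray(values, float), 3)
        return bin_force_extension([FakeTraj(ext, force)])

    def test_single_triangle_pulse(self):
        vals = [0, 0, 2, 4, 8, 4, 2, 0, 0, 0]
        peaks = detect_peaks(self._profile(vals), smooth_window=1, prominence=1.0)
        maxima = peaks.maxima()
        assert len(maxima) == 1
        assert maxima[0][0] == pytest.approx(4.5)

    def test_two_pulses_with_interior_minimum(self):
        vals = [0, 3, 8, 3, 0, 0, 0, 4, 9, 4, 0]
        peaks = detect_peaks(self._profile(vals), smooth_window=1, prominence=1.0)
        assert len(peaks.maxima()) == 2
        minima = peaks.minima()
        assert len(minima) == 1
        assert 3 < minima[0][0] < 8

    def test_flat_noise_below_prominence(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 0.01, 30)
        peaks = detect_peaks(self._profile(vals), prominence=1.0)
        assert peaks.maxima() == []


class TestKabsch:
    def test_identity(self):
        X = np.random.default_rng(1).normal(size=(10, 3))
        assert kabsch_rmsd(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=3).as_matrix()
        Y = X @ R.T + np.array([5.0, -3.0, 2.0])
        assert kabsch_rmsd(X, Y) == pytest.approx(0.0, abs=1e-8)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))

    def test_matches_quaternion_oracle(self):
        """SVD-based RMSD equals the quaternion characteristic-polynomial
        method on random coordinate pairs to 1e-6 Å."""
        rng = np.random.default_rng(4)
        for _ in range(25):
            X = rng.normal(size=(10, 3))
            Y = X + rng.normal(scale=0.7, size=(10, 3))
            assert kabsch_rmsd(X, Y) == pytest.approx(
                _quaternion_rmsd(X, Y), abs=1e-6)

    def test_triangle_inequality_after_common_superposition(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(size=(15, 3))
        frames = [superpose(ref + rng.normal(scale=0.5, size=(15, 3)), ref)
                  for _ in range(3)]

        def rms(a, b):
            return float(np.sqrt(((a - b) ** 2).sum() / len(a)))

        a, b, c = frames
        assert rms(a, c) <= rms(a, b) + rms(b, c) + 1e-6


def _quaternion_rmsd(X, Y):
    """Horn's closed-form: largest eigenvalue of the 4x4 key matrix."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S = Xc.T @ Yc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = ((Xc ** 2).sum() + (Yc ** 2).sum() - 2 * lam) / len(X)
    return float(np.sqrt(max(msd, 0.0)))


class TestSelectRepresentative:
    def test_singleton(self):
        res = select_representative([np.random.default_rng(0).normal(size=(5, 3))])
        assert res.frame_id == 0
        assert res.rmsd_sums[0] == 0.0

    def test_midpoint_frame_selected(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(8, 3))
        C = A + rng.normal(scale=1.0, size=(8, 3))
        B = 0.5 * (A + C)
        res = select_representative([A, B, C], frame_ids=[10, 20, 30])
        assert res.frame_id == 20

    def test_duplicates_tie_breaks_to_lowest_id(self):
        X = np.random.default_rng(2).normal(size=(6, 3))
        res = select_representative([X, X.copy(), X.copy()],
                                    frame_ids=[7, 3, 5])
        assert res.frame_id == 3

    def test_matches_exhaustive_oracle(self):
        """Argmin of the row sums of an independently computed all-pairs
        quaternion-RMSD table, on random ensembles up to 30 frames."""
        rng = np.random.default_rng(3)
        for m in (5, 12, 30):
            frames = [rng.normal(size=(7, 3)) for _ in range(m)]
            res = select_representative(frames)
            table = np.zeros((m, m))
            for a in range(m):
                for b in range(m):
                    if a != b:
                        table[a, b] = _quaternion_rmsd(frames[a], frames[b])
            assert res.frame_id == int(np.argmin(table.sum(axis=1)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_representative([])


class TestStructuralDescriptors:
    def test_point_cloud_collapsed(self):
        xs = np.zeros((4, 6, 3))
        rg, rgmax, rmsf = rg_rgmax_rmsf(xs)
        assert np.allclose(rg, 0) and np.allclose(rgmax, 0)
        assert np.allclose(rmsf, 0)

    def test_two_bead_closed_form(self):
        xs = np.zeros((2, 2, 3))
        xs[:, 1, 0] = 6.0       # two beads separated by d = 6
        rg, rgmax, _ = rg_rgmax_rmsf(xs)
        assert np.allclose(rg, 3.0)
        assert np.allclose(rgmax, 3.0)

    def test_static_trajectory_zero_rmsf(self):
        frame = np.random.default_rng(4).normal(size=(9, 3))
        xs = np.repeat(frame[None], 8, axis=0)
        _, _, rmsf = rg_rgmax_rmsf(xs)
        assert np.allclose(rmsf, 0, atol=1e-10)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="single frame"):
            rg_rgmax_rmsf(np.zeros((1, 5, 3)))


class TestBreakingOrder:
    pairs = [(0, 5), (1, 6), (2, 7)]

    def test_single_trajectory_order(self):
        ev = [BondEvent((1, 6), "break", 10, 50.0),
              BondEvent((0, 5), "break", 20, 100.0),
              BondEvent((2, 7), "break", 30, 150.0)]
        order = breaking_order([ev], self.pairs)
        assert [o[0] for o in order] == [(1, 6), (0, 5), (2, 7)]

    def test_reformation_only_final_break_counts(self):
        ev = [BondEvent((0, 5), "break", 10, 40.0),
              BondEvent((0, 5), "form", 15, 45.0),
              BondEvent((0, 5), "break", 40, 160.0),
              BondEvent((1, 6), "break", 20, 80.0)]
        fb = final_break_extensions(ev, self.pairs)
        assert fb[(0, 5)] == 160.0
        assert fb[(1, 6)] == 80.0
        assert fb[(2, 7)] is None
        order = breaking_order([ev], self.pairs)
        assert [o[0] for o in order] == [(1, 6), (0, 5), (2, 7)]

    def test_all_unbroken(self):
        order = breaking_order([[], []], self.pairs)
        for _, rank, votes, med in order:
            assert med is None
            assert votes == {"unbroken": 2}


def test_terminal_element_unfolds_first(toy, speed_ensembles):
    """The structured element closest to a pulling anchor (the N-terminal
    helix H1) loses its native contacts at the smallest extension among the
    labelled elements (median over 8 pulls)."""
    topo, _ = toy
    firsts = {}
    for traj in speed_ensembles[0.02]:
        prof = contact_fraction_by_element([traj], topo)
        for el, fr in prof.fractions.items():
            if el in ("T", "SS"):
                continue
            below = np.where((prof.n > 0) & (fr < 0.5))[0]
            firsts.setdefault(el, []).append(
                float(prof.centers[below[0]]) if len(below) else np.inf)
    medians = {el: float(np.median(v)) for el, v in firsts.items()}
    assert min(medians, key=medians.get) == "H1", medians


def test_contact_fraction_trivial_limits(toy):
    topo, coords = toy
    # the native conformation itself: every contact within tolerance
    native = FakeTraj([0.0, 0.2], [0, 0])
    native.xs = np.repeat(coords[None].astype(np.float32), 2, axis=0)
    prof = contact_fraction_by_element([native], topo)
    for el, fr in prof.fractions.items():
        assert np.nanmean(fr) > 0.9, el
    # a fully extended chain retains (almost) no native contacts
    n = topo.n_beads
    stretched = np.zeros((2, n, 3), dtype=np.float32)
    resid = topo.bead_residues()
    kinds = np.array([b.kind for b in topo.beads])
    stretched[:, :, 0] = resid * 3.8
    stretched[:, :, 1] = np.where(kinds == "side-center", 1.8, 0.0)
    t2 = FakeTraj([500.0, 500.5], [0, 0])
    t2.xs = stretched
    prof2 = contact_fraction_by_element([t2], topo)
    for el, fr in prof2.fractions.items():
        assert np.nanmax(fr) < 0.1, el
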