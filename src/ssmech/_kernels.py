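"""Numba force/energy kernels and the Langevin (BAOAB) integration loop.

All kernels operate on plain arrays unpacked from :class:`ssmech.potentials.CGSystem`;
they never see Python objects.  Units: Å, kcal/mol, amu, AKMA time.

Disulfide treatment modes are encoded as integers:
0 = none, 1 = dynamic (double well over all cysteine pairs + triplet
repulsion), 2 = static (harmonic), 3 = flat-bottom breaking restraint.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_NONE = 0
MODE_DYNAMIC = 1
MODE_STATIC = 2
MODE_RESTRAINT = 3



# ---------------------------------------------------------------------------
# fast deterministic Gaussian stream (xorshift128+ / Box-Muller)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _fill_gaussians(buf, state):
    """Fill buf with standard normals; state is a 2-element uint64 array
    (xorshift128+), advanced in place."""
    s0 = state[0]
    s1 = state[1]
    n = buf.shape[0]
    i = 0
    two_pi = 2.0 * np.pi
    while i < n:
        # two uniforms from two xorshift128+ draws
        x = s0
        y = s1
        s0 = y
        x ^= (x << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
        u1 = float((s1 + y) >> np.uint64(11)) * (1.0 / 9007199254740992.0)
        x = s0
        y = s1
        s0 = y
        x ^= (x << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
        u2 = float((s1 + y) >> np.uint64(11)) * (1.0 / 9007199254740992.0)
        if u1 <= 1e-300:
            u1 = 1e-300
        r = np.sqrt(-2.0 * np.log(u1))
        buf[i] = r * np.cos(two_pi * u2)
        i += 1
        if i < n:
            buf[i] = r * np.sin(two_pi * u2)
            i += 1
    state[0] = s0
    state[1] = s1


# ---------------------------------------------------------------------------
# scalar potentials
# ---------------------------------------------------------------------------

@njit(cache=True)
def u_dynss_scalar(r, A_core, D_bond, r_bond, s_bond, D_cont, r_cont, s_cont):
    """Breakable-disulfide double well. Returns (energy, -dU/dr)."""
    inv = 1.0 / r
    core = A_core * inv ** 12
    gb = np.exp(-((r - r_bond) ** 2) / (2.0 * s_bond * s_bond))
    gc = np.exp(-((r - r_cont) ** 2) / (2.0 * s_cont * s_cont))
    u = core - D_bond * gb - D_cont * gc
    du = (-12.0 * core * inv
          + D_bond * gb * (r - r_bond) / (s_bond * s_bond)
          + D_cont * gc * (r - r_cont) / (s_cont * s_cont))
    return u, -du


@njit(cache=True)
def u_flatbottom_scalar(r, k, r1, r2, r3):
    """Flat-bottom restraint with linear tail. Returns (energy, -dU/dr)."""
    if r < r1:
        d = r - r1
        return k * d * d, -2.0 * k * d
    if r <= r2:
        return 0.0, 0.0
    if r <= r3:
        d = r - r2
        return k * d * d, -2.0 * k * d
    d32 = r3 - r2
    return k * d32 * d32 + 2.0 * k * d32 * (r - r3), -2.0 * k * d32


@njit(cache=True)
def u_sss_scalar(r_ki, r_kj, a, b, c, d):
    """Triplet repulsion for cysteine k with two candidate partners i, j.

    U = a * s(r_ki) * s(r_kj), s(r) = (1 + exp(b (r - c)))^(-d): near-zero
    unless BOTH distances are in bonding range.  Returns
    (energy, dU/dr_ki, dU/dr_kj).
    """
    ei = np.exp(b * (r_ki - c))
    ej = np.exp(b * (r_kj - c))
    si = (1.0 + ei) ** (-d)
    sj = (1.0 + ej) ** (-d)
    u = a * si * sj
    dsi = -d * b * ei * (1.0 + ei) ** (-d - 1.0)
    dsj = -d * b * ej * (1.0 + ej) ** (-d - 1.0)
    return u, a * dsi * sj, a * si * dsj


# ---------------------------------------------------------------------------
# full system energy/forces
# ---------------------------------------------------------------------------

@njit(cache=True)
def compute_forces(x, F,
                   bonds, bond_k, bond_r0,
                   contacts, contact_r0, contact_eps,
                   dihedrals, dih_phi0, k_dih,
                   ev_pairs, n_ev, sigma_ev, eps_ev,
                   mode, ss_pairs, ss_r0, k_static,
                   d_par, t_par, r_par, cys_sc,
                   extra_pairs, extra_k, extra_r0,
                   ss_pair_E):
    """Fill F with -grad(U); return (E_go, E_ss, E_triplet).

    ``ss_pairs`` holds side-center bead index pairs for the mode's SS term
    (all cysteine pairs in dynamic mode, the native crosslinks otherwise);
    per-pair SS energies are written to ``ss_pair_E``.  ``extra_pairs`` are
    auxiliary harmonic restraints (construction scaffolds, tethers).
    """
    n = x.shape[0]
    F[:, :] = 0.0
    e_go = 0.0

    # harmonic bonds
    for m in range(bonds.shape[0]):
        i = bonds[m, 0]
        j = bonds[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - bond_r0[m]
        e_go += bond_k[m] * d * d
        if r > 1e-12:
            fmag = -2.0 * bond_k[m] * d / r
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[i, 2] += fmag * dz
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
            F[j, 2] -= fmag * dz

    # auxiliary harmonic restraints
    for m in range(extra_pairs.shape[0]):
        i = extra_pairs[m, 0]
        j = extra_pairs[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - extra_r0[m]
        e_go += extra_k[m] * d * d
        if r > 1e-12:
            fmag = -2.0 * extra_k[m] * d / r
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[i, 2] += fmag * dz
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
            F[j, 2] -= fmag * dz

    # 12-10 native-contact wells
    for m in range(contacts.shape[0]):
        i = contacts[m, 0]
        j = contacts[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        s = contact_r0[m] / r
        s2 = s * s
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        eps = contact_eps[m]
        e_go += eps * (5.0 * s12 - 6.0 * s10)
        # dU/dr = eps*(-60 s12 + 60 s10)/r ; force = -dU/dr
        fmag = eps * 60.0 * (s12 - s10) / r2  # = -dU/dr / r
        F[i, 0] += fmag * dx
        F[i, 1] += fmag * dy
        F[i, 2] += fmag * dz
        F[j, 0] -= fmag * dx
        F[j, 1] -= fmag * dy
        F[j, 2] -= fmag * dz

    # quartic excluded volume: eps_ev*(1-(r/sigma)^2)^2 for r < sigma,
    # over an explicit (possibly distance-pruned) pair list
    sig2 = sigma_ev * sigma_ev
    for m in range(n_ev):
        i = ev_pairs[m, 0]
        j = ev_pairs[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= sig2:
            continue
        q = 1.0 - r2 / sig2
        e_go += eps_ev * q * q
        # dU/dr2 = -2 eps q / sig2 ; F = -dU/dr * rhat = -2 dU/dr2 * dx
        fmag = 4.0 * eps_ev * q / sig2
        F[i, 0] += fmag * dx
        F[i, 1] += fmag * dy
        F[i, 2] += fmag * dz
        F[j, 0] -= fmag * dx
        F[j, 1] -= fmag * dy
        F[j, 2] -= fmag * dz

    # cosine pseudo-dihedrals: k*(1 - cos(phi - phi0))
    for m in range(dihedrals.shape[0]):
        i1 = dihedrals[m, 0]
        i2 = dihedrals[m, 1]
        i3 = dihedrals[m, 2]
        i4 = dihedrals[m, 3]
        b1x = x[i2, 0] - x[i1, 0]
        b1y = x[i2, 1] - x[i1, 1]
        b1z = x[i2, 2] - x[i1, 2]
        b2x = x[i3, 0] - x[i2, 0]
        b2y = x[i3, 1] - x[i2, 1]
        b2z = x[i3, 2] - x[i2, 2]
        b3x = x[i4, 0] - x[i3, 0]
        b3y = x[i4, 1] - x[i3, 1]
        b3z = x[i4, 2] - x[i3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-10 or n2sq < 1e-10 or b2n < 1e-10:
            continue
        # phi = atan2((n1 x n2).b2hat, n1.n2)
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        sinp = (mx * b2x + my * b2y + mz * b2z) / b2n
        cosp = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sinp, cosp)
        e_go += k_dih * (1.0 - np.cos(phi - dih_phi0[m]))
        dU = k_dih * np.sin(phi - dih_phi0[m])  # dU/dphi
        # Blondel-Karplus gradients
        g1 = -b2n / n1sq
        g4 = b2n / n2sq
        dp1x = g1 * n1x
        dp1y = g1 * n1y
        dp1z = g1 * n1z
        dp4x = g4 * n2x
        dp4y = g4 * n2y
        dp4z = g4 * n2z
        t12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        t32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        dp2x = -(1.0 + t12) * dp1x + t32 * dp4x
        dp2y = -(1.0 + t12) * dp1y + t32 * dp4y
        dp2z = -(1.0 + t12) * dp1z + t32 * dp4z
        dp3x = t12 * dp1x - (1.0 + t32) * dp4x
        dp3y = t12 * dp1y - (1.0 + t32) * dp4y
        dp3z = t12 * dp1z - (1.0 + t32) * dp4z
        F[i1, 0] -= dU * dp1x
        F[i1, 1] -= dU * dp1y
        F[i1, 2] -= dU * dp1z
        F[i2, 0] -= dU * dp2x
        F[i2, 1] -= dU * dp2y
        F[i2, 2] -= dU * dp2z
        F[i3, 0] -= dU * dp3x
        F[i3, 1] -= dU * dp3y
        F[i3, 2] -= dU * dp3z
        F[i4, 0] -= dU * dp4x
        F[i4, 1] -= dU * dp4y
        F[i4, 2] -= dU * dp4z

    # --- disulfide terms -------------------------------------------------
    e_ss = 0.0
    e_trip = 0.0
    for m in range(ss_pairs.shape[0]):
        i = ss_pairs[m, 0]
        j = ss_pairs[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if mode == MODE_DYNAMIC:
            u, fr = u_dynss_scalar(r, d_par[0], d_par[1], d_par[2], d_par[3],
                                   d_par[4], d_par[5], d_par[6])
        elif mode == MODE_STATIC:
            dd = r - ss_r0[m]
            u = k_static * dd * dd
            fr = -2.0 * k_static * dd
        elif mode == MODE_RESTRAINT:
            u, fr = u_flatbottom_scalar(r, r_par[0], r_par[1], r_par[2], r_par[3])
        else:
            u = 0.0
            fr = 0.0
        ss_pair_E[m] = u
        e_ss += u
        if r > 1e-12:
            fmag = fr / r
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[i, 2] += fmag * dz
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
            F[j, 2] -= fmag * dz

    if mode == MODE_DYNAMIC:
        ncys = cys_sc.shape[0]
        rmat = np.empty((ncys, ncys))
        for a in range(ncys):
            rmat[a, a] = 0.0
            for b in range(a + 1, ncys):
                dx = x[cys_sc[a], 0] - x[cys_sc[b], 0]
                dy = x[cys_sc[a], 1] - x[cys_sc[b], 1]
                dz = x[cys_sc[a], 2] - x[cys_sc[b], 2]
                rmat[a, b] = rmat[b, a] = np.sqrt(dx * dx + dy * dy + dz * dz)
        # beyond r_cut each sigmoid factor is < e^-12: negligible
        r_cut = t_par[2] + 12.0 / (t_par[1] * t_par[3])
        for kc in range(ncys):
            kidx = cys_sc[kc]
            for ic in range(ncys):
                if ic == kc or rmat[kc, ic] > r_cut:
                    continue
                for jc in range(ic + 1, ncys):
                    if jc == kc or rmat[kc, jc] > r_cut:
                        continue
                    iidx = cys_sc[ic]
                    jidx = cys_sc[jc]
                    dxi = x[kidx, 0] - x[iidx, 0]
                    dyi = x[kidx, 1] - x[iidx, 1]
                    dzi = x[kidx, 2] - x[iidx, 2]
                    rki = rmat[kc, ic]
                    dxj = x[kidx, 0] - x[jidx, 0]
                    dyj = x[kidx, 1] - x[jidx, 1]
                    dzj = x[kidx, 2] - x[jidx, 2]
                    rkj = rmat[kc, jc]
                    u, duki, dukj = u_sss_scalar(rki, rkj, t_par[0], t_par[1],
                                                 t_par[2], t_par[3])
                    e_trip += u
                    if rki > 1e-12:
                        fm = -duki / rki
                        F[kidx, 0] += fm * dxi
                        F[kidx, 1] += fm * dyi
                        F[kidx, 2] += fm * dzi
                        F[iidx, 0] -= fm * dxi
                        F[iidx, 1] -= fm * dyi
                        F[iidx, 2] -= fm * dzi
                    if rkj > 1e-12:
                        fm = -dukj / rkj
                        F[kidx, 0] += fm * dxj
                        F[kidx, 1] += fm * dyj
                        F[kidx, 2] += fm * dzj
                        F[jidx, 0] -= fm * dxj
                        F[jidx, 1] -= fm * dyj
                        F[jidx, 2] -= fm * dzj

    return e_go, e_ss, e_trip


# ---------------------------------------------------------------------------
# BAOAB Langevin integrator with optional constant-velocity pulling
# ---------------------------------------------------------------------------

@njit(cache=True)
def integrate(x, v, masses, dt, n_steps, save_every, gamma, kT, seed,
              bonds, bond_k, bond_r0,
              contacts, contact_r0, contact_eps,
              dihedrals, dih_phi0, k_dih,
              ev_pairs, n_ev, sigma_ev, eps_ev,
              mode, ss_pairs, ss_r0, k_static,
              d_par, t_par, r_par, cys_sc,
              extra_pairs, extra_k, extra_r0,
              pull_on, anchor_i, anchor_j, fix_pt, mov_pt0, pull_dir,
              speed, k_spring, native_sep,
              log_pairs,
              out_x, out_ext, out_force, out_epot, out_ess, out_ssd):
    """BAOAB Langevin loop; gamma == 0 and kT == 0 reduce to velocity Verlet.

    The spring tethers anchor_i to ``fix_pt`` and anchor_j to a point moving
    from ``mov_pt0`` along ``pull_dir`` at ``speed`` (Å per internal time).
    Saves every ``save_every`` steps (including step 0); returns the number
    of frames saved (< expected on numeric blow-up).
    """
    rng_state = np.empty(2, dtype=np.uint64)
    rng_state[0] = _splitmix64(np.uint64(seed))
    rng_state[1] = _splitmix64(rng_state[0])
    n = x.shape[0]
    xi = np.empty(3 * n)
    F = np.zeros((n, 3))
    ss_pair_E = np.zeros(max(ss_pairs.shape[0], 1))

    # excluded-volume neighbor list over the static pair list, rebuilt
    # periodically; the skin comfortably exceeds the possible drift
    nl_every = 50
    skin = 1.2
    nl_cut2 = (sigma_ev + skin) ** 2
    nl = np.empty_like(ev_pairs)
    n_nl = 0
    for m in range(n_ev):
        i = ev_pairs[m, 0]
        j = ev_pairs[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        if dx * dx + dy * dy + dz * dz < nl_cut2:
            nl[n_nl, 0] = i
            nl[n_nl, 1] = j
            n_nl += 1

    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
    else:
        c1 = 1.0
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    sd = c2 / np.sqrt(masses)

    e_go, e_ss, e_tr = compute_forces(
        x, F, bonds, bond_k, bond_r0, contacts, contact_r0, contact_eps,
        dihedrals, dih_phi0, k_dih, nl, n_nl, sigma_ev, eps_ev,
        mode, ss_pairs, ss_r0, k_static, d_par, t_par, r_par, cys_sc,
        extra_pairs, extra_k, extra_r0, ss_pair_E)

    n_saved = 0
    for step in range(n_steps + 1):
        t = step * dt
        # spring forces on anchors (added after conservative forces)
        if pull_on == 1:
            mx = mov_pt0[0] + pull_dir[0] * speed * t
            my = mov_pt0[1] + pull_dir[1] * speed * t
            mz = mov_pt0[2] + pull_dir[2] * speed * t
            F[anchor_i, 0] += -k_spring * (x[anchor_i, 0] - fix_pt[0])
            F[anchor_i, 1] += -k_spring * (x[anchor_i, 1] - fix_pt[1])
            F[anchor_i, 2] += -k_spring * (x[anchor_i, 2] - fix_pt[2])
            F[anchor_j, 0] += -k_spring * (x[anchor_j, 0] - mx)
            F[anchor_j, 1] += -k_spring * (x[anchor_j, 1] - my)
            F[anchor_j, 2] += -k_spring * (x[anchor_j, 2] - mz)

        if step % save_every == 0:
            idx = step // save_every
            for a in range(n):
                out_x[idx, a, 0] = x[a, 0]
                out_x[idx, a, 1] = x[a, 1]
                out_x[idx, a, 2] = x[a, 2]
            dax = x[anchor_i, 0] - x[anchor_j, 0]
            day = x[anchor_i, 1] - x[anchor_j, 1]
            daz = x[anchor_i, 2] - x[anchor_j, 2]
            sep = np.sqrt(dax * dax + day * day + daz * daz)
            out_ext[idx] = sep - native_sep
            if pull_on == 1:
                mx = mov_pt0[0] + pull_dir[0] * speed * t
                my = mov_pt0[1] + pull_dir[1] * speed * t
                mz = mov_pt0[2] + pull_dir[2] * speed * t
                out_force[idx] = k_spring * ((mx - x[anchor_j, 0]) * pull_dir[0]
                                             + (my - x[anchor_j, 1]) * pull_dir[1]
                                             + (mz - x[anchor_j, 2]) * pull_dir[2])
            else:
                out_force[idx] = 0.0
            out_epot[idx] = e_go + e_ss + e_tr
            out_ess[idx] = e_ss + e_tr
            for p in range(log_pairs.shape[0]):
                li = log_pairs[p, 0]
                lj = log_pairs[p, 1]
                ddx = x[li, 0] - x[lj, 0]
                ddy = x[li, 1] - x[lj, 1]
                ddz = x[li, 2] - x[lj, 2]
                out_ssd[idx, p] = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            n_saved = idx + 1

        if step == n_steps:
            break

        # B (half kick)
        for a in range(n):
            inv_m = 1.0 / masses[a]
            v[a, 0] += 0.5 * dt * F[a, 0] * inv_m
            v[a, 1] += 0.5 * dt * F[a, 1] * inv_m
            v[a, 2] += 0.5 * dt * F[a, 2] * inv_m
        # A (half drift)
        for a in range(n):
            x[a, 0] += 0.5 * dt * v[a, 0]
            x[a, 1] += 0.5 * dt * v[a, 1]
            x[a, 2] += 0.5 * dt * v[a, 2]
        # O (thermostat)
        if gamma > 0.0 and kT > 0.0:
            _fill_gaussians(xi, rng_state)
            for a in range(n):
                v[a, 0] = c1 * v[a, 0] + sd[a] * xi[3 * a]
                v[a, 1] = c1 * v[a, 1] + sd[a] * xi[3 * a + 1]
                v[a, 2] = c1 * v[a, 2] + sd[a] * xi[3 * a + 2]
        # A (half drift)
        for a in range(n):
            x[a, 0] += 0.5 * dt * v[a, 0]
            x[a, 1] += 0.5 * dt * v[a, 1]
            x[a, 2] += 0.5 * dt * v[a, 2]
        # blow-up guard
        bad = False
        for a in range(n):
            if (abs(x[a, 0]) > 1e6) or (abs(x[a, 1]) > 1e6) or (abs(x[a, 2]) > 1e6):
                bad = True
                break
        if bad:
            return -n_saved
        # refresh neighbor list, recompute forces, B (half kick)
        if (step + 1) % nl_every == 0:
            n_nl = 0
            for m in range(n_ev):
                i = ev_pairs[m, 0]
                j = ev_pairs[m, 1]
                dx = x[i, 0] - x[j, 0]
                dy = x[i, 1] - x[j, 1]
                dz = x[i, 2] - x[j, 2]
                if dx * dx + dy * dy + dz * dz < nl_cut2:
                    nl[n_nl, 0] = i
                    nl[n_nl, 1] = j
                    n_nl += 1
        e_go, e_ss, e_tr = compute_forces(
            x, F, bonds, bond_k, bond_r0, contacts, contact_r0, contact_eps,
            dihedrals, dih_phi0, k_dih, nl, n_nl, sigma_ev, eps_ev,
            mode, ss_pairs, ss_r0, k_static, d_par, t_par, r_par, cys_sc,
            extra_pairs, extra_k, extra_r0, ss_pair_E)
        if pull_on == 1:
            t2 = (step + 1) * dt
            mx = mov_pt0[0] + pull_dir[0] * speed * t2
            my = mov_pt0[1] + pull_dir[1] * speed * t2
            mz = mov_pt0[2] + pull_dir[2] * speed * t2
            F[anchor_i, 0] += -k_spring * (x[anchor_i, 0] - fix_pt[0])
            F[anchor_i, 1] += -k_spring * (x[anchor_i, 1] - fix_pt[1])
            F[anchor_i, 2] += -k_spring * (x[anchor_i, 2] - fix_pt[2])
            F[anchor_j, 0] += -k_spring * (x[anchor_j, 0] - mx)
            F[anchor_j, 1] += -k_spring * (x[anchor_j, 1] - my)
            F[anchor_j, 2] += -k_spring * (x[anchor_j, 2] - mz)
        for a in range(n):
            inv_m = 1.0 / masses[a]
            v[a, 0] += 0.5 * dt * F[a, 0] * inv_m
            v[a, 1] += 0.5 * dt * F[a, 1] * inv_m
            v[a, 2] += 0.5 * dt * F[a, 2] * inv_m
        # restore pure conservative forces for the next iteration's bookkeeping
        if pull_on == 1:
            t2 = (step + 1) * dt
            mx = mov_pt0[0] + pull_dir[0] * speed * t2
            my = mov_pt0[1] + pull_dir[1] * speed * t2
            mz = mov_pt0[2] + pull_dir[2] * speed * t2
            F[anchor_i, 0] -= -k_spring * (x[anchor_i, 0] - fix_pt[0])
            F[anchor_i, 1] -= -k_spring * (x[anchor_i, 1] - fix_pt[1])
            F[anchor_i, 2] -= -k_spring * (x[anchor_i, 2] - fix_pt[2])
            F[anchor_j, 0] -= -k_spring * (x[anchor_j, 0] - mx)
            F[anchor_j, 1] -= -k_spring * (x[anchor_j, 1] - my)
            F[anchor_j, 2] -= -k_spring * (x[anchor_j, 2] - mz)

    return n_saved
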