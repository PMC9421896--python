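"""Unit system and conversion helpers.

Internal units everywhere in this package: length in Å, energy in kcal/mol,
mass in amu (g/mol).  The induced time unit is sqrt(amu Å² mol / kcal)
= 48.88821 fs (the AKMA time unit); the coarse-grained molecular time unit
(MTU) used to express pulling speeds is 4.89 fs.  Forces are converted to pN
only at the reporting boundary.
"""

from __future__ import annotations

import math

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: 1 kcal/mol/Å expressed in pN (fixed reporting constant)
KCAL_PER_MOL_ANG_TO_PN = 69.479

#: AKMA time unit in fs: sqrt(1 amu * 1 Å² / (1 kcal/mol))
AKMA_FS = 48.88821

#: coarse-grained molecular time unit in fs
MTU_FS = 4.89

#: speed-up factor of coarse-grained dynamics relative to physical time
CG_TIME_SCALE = 1000.0


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def cg_speed_to_mps(speed_ang_per_mtu: float, scale_factor: float = CG_TIME_SCALE) -> float:
    """Convert a coarse-grained pulling speed (Å/MTU) to an effective m/s.

    The raw conversion is ``speed * 1e-10 m / 4.89e-15 s``; the coarse-grained
    model runs roughly ``scale_factor`` (default 1000) times faster than
    physical time, so the reported effective speed is divided by it.  The
    result is rounded to 2 significant figures, matching how such speeds are
    conventionally quoted; pass ``scale_factor=1`` for the raw physical speed.
    """
    if speed_ang_per_mtu <= 0:
        raise ValueError("pulling speed must be > 0")
    mps = (speed_ang_per_mtu * 1e-10 / (MTU_FS * 1e-15)) / scale_factor
    return round_sig(mps, 2)


def aa_speed_to_mps(speed_ang_per_ns: float) -> float:
    """Convert an all-atom pulling speed (Å/ns) to m/s (factor 0.1)."""
    if speed_ang_per_ns < 0:
        raise ValueError("pulling speed must be >= 0")
    return speed_ang_per_ns * 0.1


def force_to_pN(f_kcal_per_mol_ang: float) -> float:
    """Convert a force from kcal/mol/Å to pN."""
    return f_kcal_per_mol_ang * KCAL_PER_MOL_ANG_TO_PN


def fs_to_internal(t_fs: float) -> float:
    """Convert fs to internal (AKMA) time units."""
    return t_fs / AKMA_FS


def internal_to_fs(t_internal: float) -> float:
    """Convert internal (AKMA) time units to fs."""
    return t_internal * AKMA_FS
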