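"""Shared fixtures: small folds and the simulation ensembles reused across
analysis and acceptance tests.  Ensembles are session-scoped because the
pulls are the expensive part of the suite; every run is fully determined by
its protocol seed."""

from __future__ import annotations

import numpy as np
import pytest

from ssmech.dynamics import SMDProtocol, run_smd
from ssmech.potentials import RedoxModel
from ssmech.topology import (ToyFoldSpec, default_toy_spec, generate_toy_fold,
                             rnase_mimic_spec)

#: pulling speed (Å/MTU) used for the ensemble fixtures
ENSEMBLE_SPEED = 0.02
N_SEEDS = 8


@pytest.fixture(scope="session")
def toy():
    """40-residue helix/sheet fold with two crosslinks."""
    return generate_toy_fold(default_toy_spec(0))


@pytest.fixture(scope="session")
def mimic():
    """124-residue RNase-A mimic with the four published crosslinks."""
    return generate_toy_fold(rnase_mimic_spec(0))


@pytest.fixture(scope="session")
def tiny_pair():
    """Minimal crosslinked chain: one disulfide in an 8-residue loop."""
    spec = ToyFoldSpec(n_residues=8, blocks=(("loop", 8),),
                       crosslinks=((2, 5),), seed=1)
    return generate_toy_fold(spec)


def _pull(topo, coords, redox, speed, n_steps, seed, temperature=300.0):
    proto = SMDProtocol(speed=speed, n_steps=n_steps, seed=seed,
                        temperature=temperature)
    traj, _ = run_smd(topo, coords, None, redox, proto)
    return traj


@pytest.fixture(scope="session")
def speed_ensembles(toy):
    """Toy-fold pulls at three speeds of the coarse-grained grid (highly
    oxidizing dynamic bonds), 8 seeds each; step counts scaled so every run
    covers the same spring travel."""
    topo, coords = toy
    redox = RedoxModel(mode="dynamic").with_depth(11.0)
    out = {}
    for speed in (0.005, 0.01, 0.02):
        n_steps = int(round(0.02 / speed * 80_000))
        out[speed] = [_pull(topo, coords, redox, speed, n_steps, 100 + s)
                      for s in range(N_SEEDS)]
    return out


@pytest.fixture(scope="session")
def cold_ensemble(toy):
    """Toy-fold pulls at 278 K, fastest speed (same seeds as the 300 K set)."""
    topo, coords = toy
    redox = RedoxModel(mode="dynamic").with_depth(11.0)
    return [_pull(topo, coords, redox, 0.02, 80_000, 100 + s, temperature=278.0)
            for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def contrast_ensembles(mimic):
    """RNase-mimic pulls under the four disulfide treatments, 8 seeds each.

    The static runs are shorter: the chain hits its inextensibility ceiling
    early and further pulling only loads the spring.
    """
    topo, coords = mimic
    conditions = {
        "none": (RedoxModel(mode="none"), 250_000),
        "weak": (RedoxModel(mode="dynamic").with_depth(5.5), 250_000),
        "high": (RedoxModel(mode="dynamic").with_depth(11.0), 250_000),
        "static": (RedoxModel(mode="static"), 130_000),
    }
    return {mode: [_pull(topo, coords, redox, ENSEMBLE_SPEED, nst, 400 + s)
                   for s in range(N_SEEDS)]
            for mode, (redox, nst) in conditions.items()}


@pytest.fixture(scope="session")
def rupture_forces(tiny_pair):
    """Mean rupture force of the single tethered pair at both redox depths."""
    topo, coords = tiny_pair
    out = {}
    for depth in (5.5, 11.0):
        redox = RedoxModel(mode="dynamic").with_depth(depth)
        forces = []
        for s in range(N_SEEDS):
            traj = _pull(topo, coords, redox, 0.005, 60_000, 200 + s)
            breaks = [e for e in traj.events if e.kind == "break"]
            if breaks:
                k = np.searchsorted(traj.steps, breaks[-1].step)
                forces.append(traj.force_pN[:k + 1].max())
            else:
                forces.append(traj.force_pN.max())
        out[depth] = np.array(forces)
    return out
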