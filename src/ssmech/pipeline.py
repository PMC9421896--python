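"""Top-level driver: generate -> run ensemble -> analyze -> report.

Everything is reproducible from the configuration plus the master seed;
each output file carries a header with the configuration hash and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, dynamics, topology
from .config import RunConfig, config_hash
from .potentials import RedoxModel

log = logging.getLogger("ssmech")


@dataclass
class ConditionResult:
    label: str
    mode: str
    depth: float | None
    speed: float
    trajectories: list
    profile: analysis.ForceExtensionProfile
    peaks: analysis.PeakSet
    bond_fractions: analysis.FractionProfile | None
    breaking: list
    last_break_extensions: list = field(default_factory=list)
    n_failed: int = 0


def run_condition(topo, coords, cfg: RunConfig, label: str, mode: str,
                  depth: float | None, speed: float) -> ConditionResult:
    redox = replace(cfg.redox_base, mode=mode)
    if depth is not None:
        redox = redox.with_depth(depth)
    trajs, n_failed = [], 0
    for rep in range(cfg.n_seeds):
        proto = replace(cfg.protocol, speed=speed,
                        seed=cfg.trajectory_seed(label, rep))
        try:
            traj, _ = dynamics.run_smd(topo, coords, cfg.go, redox, proto)
            trajs.append(traj)
        except dynamics.NumericalBlowupError as err:
            n_failed += 1
            log.warning("trajectory %s/%d failed: %s", label, rep, err)
    if not trajs:
        raise RuntimeError(f"all trajectories failed for condition {label}")

    profile = analysis.bin_force_extension(trajs, cfg.bin_width)
    peaks = analysis.detect_peaks(profile)
    native_pairs = [tuple(p) for p in topo.crosslinks]
    bond_fractions = (analysis.bond_fraction_vs_extension(
        trajs, cutoff=cfg.ss_cutoff, bin_width=cfg.bin_width)
        if topo.cysteines else None)
    breaking = (analysis.breaking_order([t.events for t in trajs], native_pairs)
                if native_pairs and mode not in ("static",) else [])
    last_breaks = []
    for t in trajs:
        fb = analysis.final_break_extensions(t.events, native_pairs)
        vals = [v for v in fb.values() if v is not None]
        last_breaks.append(max(vals) if len(vals) == len(native_pairs) else None)
    return ConditionResult(label=label, mode=mode, depth=depth, speed=speed,
                           trajectories=trajs, profile=profile, peaks=peaks,
                           bond_fractions=bond_fractions, breaking=breaking,
                           last_break_extensions=last_breaks, n_failed=n_failed)


def summarize(results) -> pd.DataFrame:
    rows = []
    for r in results:
        maxima = r.peaks.maxima()
        peak_f = max((f for _, f, _ in maxima), default=np.nan)
        finite_lb = [e for e in r.last_break_extensions if e is not None]
        rows.append({
            "condition": r.label, "mode": r.mode,
            "D_bond": r.depth if r.depth is not None else np.nan,
            "speed_A_per_MTU": r.speed,
            "n_traj": len(r.trajectories), "n_failed": r.n_failed,
            "max_peak_force_pN": peak_f,
            "n_force_maxima": len(maxima),
            "median_last_break_ext_A": (float(np.median(finite_lb))
                                        if finite_lb else np.nan),
            "n_fully_broken": len(finite_lb),
        })
    return pd.DataFrame(rows)


def pipeline_run(cfg: RunConfig, outdir) -> pd.DataFrame:
    """Execute the full grid and write profiles, peak tables, bond-fraction
    curves, breaking orders and a cross-mode summary under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    header = f"config_hash={chash} master_seed={cfg.master_seed}"

    topo, coords = topology.generate_toy_fold(cfg.toy_fold)
    topology.write_topology(topo, outdir / "topology")
    topology.write_pdb(topo, coords, outdir / "native.pdb")

    results = []
    for label, mode, depth, speed in cfg.conditions():
        res = run_condition(topo, coords, cfg, label, mode, depth, speed)
        results.append(res)
        analysis.write_profile(res.profile, outdir / f"{label}_profile.tsv", header)
        with open(outdir / f"{label}_peaks.tsv", "w") as fh:
            fh.write(f"# {header}\nextension_A\tforce_pN\tkind\n")
            for e, f, kind in res.peaks.peaks:
                fh.write(f"{e:.2f}\t{f:.4f}\t{kind}\n")
        if res.bond_fractions is not None:
            analysis.write_fractions(res.bond_fractions,
                                     outdir / f"{label}_bond_fractions.tsv", header)
        for i, t in enumerate(res.trajectories):
            dynamics.write_force_log(t, outdir / f"{label}_traj{i}.tsv", header)
            dynamics.write_events(t.events, outdir / f"{label}_traj{i}_events.tsv",
                                  header)
        if res.breaking:
            with open(outdir / f"{label}_breaking_order.tsv", "w") as fh:
                fh.write(f"# {header}\npair\tmedian_rank\tmedian_ext_A\tvotes\n")
                for p, mr, votes, me in res.breaking:
                    fh.write(f"{p[0] + 1}-{p[1] + 1}\t{mr:.1f}\t"
                             f"{'NA' if me is None else f'{me:.2f}'}\t{votes}\n")

    summary = summarize(results)
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write(f"# {header}\n")
        summary.to_csv(fh, sep="\t", index=False, float_format="%.4f")
    return summary
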