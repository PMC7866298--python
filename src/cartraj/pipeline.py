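"""End-to-end analysis over two conditions, emitting tables.

``run_analysis`` executes the full protocol on a pair of replicate sets
(methylated vs unmethylated R146): equilibration discard and 1-frame/ns
sampling, per-residue RMSF (core and backbone rules), the four stacking COM
distances, the stripped-SASA protocol, H-bond counts and frequency-classified
edges, pooled RMS2D matrices (core/backbone, with and without (m)R146),
cross-trajectory divergence and core-vs-backbone gaps, and the replicate-level
Welch/Bonferroni and bootstrap tests.  Tables, not figures, are the primary
output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hbonds, stacking, stats, superpose
from .io_model import ReplicateSet, Trajectory, production_window, read_pdb, \
    read_trajectory
from .selections import RoleMap, core_atoms, resolve_roles, \
    selection_for_rule, ANTICODON_ROLES, CAR_ROLES, ROLE_LABELS

logger = logging.getLogger(__name__)

#: stacking COM distance pairs, in reporting order
COM_PAIRS = (
    ("nt35", "nt34"),
    ("nt34", "C1054"),
    ("C1054", "A1196"),
    ("A1196", "R146"),
)

#: focus residues of the H-bond count panel
HBOND_FOCUS_ROLES = ("plus1_G1", "plus1_C2", "plus1_U3",
                     "Asite_C2", "Asite_U3")


@dataclass
class RunConfig:
    """Analysis configuration; every protocol numeral appears here as an
    explicit default, never as a hidden constant."""

    conditions: dict[str, list[str]] = field(default_factory=dict)
    topologies: dict[str, str] = field(default_factory=dict)
    role_map: dict = field(default_factory=dict)
    equilibration_ns: float = 20.0
    frame_step_ns: float = 1.0
    frame_interval_ns: float = 1.0
    hbond_dist_cutoff: float = hbonds.DEFAULT_DIST_CUTOFF
    hbond_angle_cutoff: float = hbonds.DEFAULT_ANGLE_CUTOFF
    hbond_weak_threshold: float = hbonds.WEAK_THRESHOLD
    hbond_strong_threshold: float = hbonds.STRONG_THRESHOLD
    sasa_probe: float = stacking.DEFAULT_PROBE_RADIUS
    sasa_points: int = stacking.DEFAULT_SPHERE_POINTS
    bootstrap_samples: int = 10_000
    seed: int = 0
    bonferroni: dict = field(default_factory=lambda: {
        "rmsf": 12, "com": 4, "hbond": 5, "sasa": 1})
    output_dir: str = "cartraj_report"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Report:
    rmsf: pd.DataFrame
    com: pd.DataFrame
    sasa: pd.DataFrame
    hbond_counts: pd.DataFrame
    hbond_edges: pd.DataFrame
    # keyed by (condition, rule, variant, schedule)
    rms2d: dict[tuple[str, str, str, str], superpose.Rms2dMatrix]
    divergence: pd.DataFrame
    gaps: pd.DataFrame
    tests: pd.DataFrame
    bootstrap: pd.DataFrame
    metadata: dict

    def write(self, outdir) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("rmsf", "com", "sasa", "hbond_counts", "hbond_edges",
                     "divergence", "gaps", "tests", "bootstrap"):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t",
                                       index=False)
        for (cond, rule, variant, schedule), mat in self.rms2d.items():
            stem = f"rms2d_{cond}_{rule}_{variant}_{schedule}"
            np.savetxt(out / f"{stem}.tsv", mat.values, delimiter="\t",
                       fmt="%.4f")
            pd.DataFrame({
                "trajectory": mat.trajectory_ids, "time_ns": mat.times,
            }).to_csv(out / f"{stem}_frames.tsv", sep="\t", index=False)
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)
        return out


def _per_replicate_production(reps: ReplicateSet, step_ns: float,
                              ) -> list[Trajectory]:
    return [production_window(t, reps.equilibration_ns, step_ns)
            for t in reps.trajectories]


def _condition_tables(cond: str, production: list[Trajectory],
                      role_map: RoleMap, config: RunConfig):
    top = production[0].topology
    aliases = role_map.methylarginine_aliases
    role_residues = {r: role_map[r] for r in ROLE_LABELS}
    guan_sel = core_atoms(top, [role_map["R146"]], aliases)
    a1196_sel = core_atoms(top, [role_map["A1196"]])

    rmsf_rows, com_rows, sasa_rows, count_rows = [], [], [], []
    for rep_id, traj in enumerate(production):
        for rule in ("core", "backbone"):
            table = superpose.rmsf(traj, top, role_residues, rule,
                                   methylarginine_aliases=aliases)
            table["condition"] = cond
            table["replicate"] = rep_id
            rmsf_rows.append(table)
        for role_a, role_b in COM_PAIRS:
            sel_a = core_atoms(top, [role_map[role_a]], aliases)
            sel_b = core_atoms(top, [role_map[role_b]], aliases)
            series = stacking.com_distance_series(
                traj, sel_a, sel_b, f"{role_a}-{role_b}")
            com_rows.append({
                "condition": cond, "replicate": rep_id,
                "pair": f"{role_a}-{role_b}",
                "mean_distance_A": float(series["distance_A"].mean()),
                "n_frames": traj.n_frames})
        sasa = stacking.stripped_sasa(traj, guan_sel, a1196_sel,
                                      config.sasa_probe, config.sasa_points)
        sasa_rows.append({
            "condition": cond, "replicate": rep_id,
            "mean_sasa_AB_A2": float(sasa["sasa_AB_A2"].mean()),
            "mean_buried_A2": float(sasa["buried_A2"].mean()),
            "probe_A": config.sasa_probe, "n_frames": traj.n_frames})
        counts = hbonds.per_residue_counts(
            traj, role_map, HBOND_FOCUS_ROLES,
            CAR_ROLES + ANTICODON_ROLES,
            config.hbond_dist_cutoff, config.hbond_angle_cutoff)
        counts["condition"] = cond
        counts["replicate"] = rep_id
        count_rows.append(counts)

    pooled = _concatenate(production)
    edges = hbonds.occupancy(
        pooled, role_map, HBOND_FOCUS_ROLES, CAR_ROLES + ANTICODON_ROLES,
        config.hbond_dist_cutoff, config.hbond_angle_cutoff,
        config.hbond_weak_threshold, config.hbond_strong_threshold)
    edges["condition"] = cond
    return (pd.concat(rmsf_rows, ignore_index=True),
            pd.DataFrame(com_rows), pd.DataFrame(sasa_rows),
            pd.concat(count_rows, ignore_index=True), edges)


def _concatenate(trajectories: list[Trajectory]) -> Trajectory:
    coords = np.concatenate([t.coords for t in trajectories])
    # synthesize strictly-increasing times across the pool
    times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(trajectories[0].topology, coords, times)


def _schedule_groups(production: list[Trajectory]) -> dict[str, list[int]]:
    """Group replicate indices by duration; RMS2D pools frames only within
    a schedule group (e.g. the 60-ns runs separately from the 100-ns runs)."""
    groups: dict[str, list[int]] = {}
    for i, t in enumerate(production):
        key = f"{t.times[-1] - t.times[0]:g}ns"
        groups.setdefault(key, []).append(i)
    return {k: v for k, v in groups.items() if len(v) >= 2}


def _rms2d_variants(cond: str, production: list[Trajectory],
                    role_map: RoleMap):
    top = production[0].topology
    aliases = role_map.methylarginine_aliases
    out: dict[tuple[str, str, str, str], superpose.Rms2dMatrix] = {}
    twelve = [role_map[r] for r in ROLE_LABELS]
    eleven = [role_map[r] for r in ROLE_LABELS if r != "R146"]
    for schedule, indices in _schedule_groups(production).items():
        group = [production[i] for i in indices]
        for rule in ("core", "backbone"):
            for variant, residues in (("12res", twelve), ("11res", eleven)):
                sel = selection_for_rule(top, residues, rule, aliases)
                out[(cond, rule, variant, schedule)] = superpose.rms2d(
                    group, sel, rule=rule)
    return out


def analyze_replicates(replicate_sets: dict[str, ReplicateSet],
                       config: RunConfig) -> Report:
    """Run the full analysis on prepared replicate sets (two conditions)."""
    if len(replicate_sets) != 2:
        raise ValueError("the analysis compares exactly two conditions")
    for cond, reps in replicate_sets.items():
        if len(reps.trajectories) < 2:
            raise ValueError(
                f"condition {cond!r} has fewer than 2 replicates; "
                "replicate-level tests are impossible")

    production: dict[str, list[Trajectory]] = {}
    role_maps: dict[str, RoleMap] = {}
    for cond, reps in replicate_sets.items():
        production[cond] = _per_replicate_production(reps,
                                                     config.frame_step_ns)
        role_maps[cond] = resolve_roles(config.role_map,
                                        production[cond][0].topology)
        logger.info("condition %s: %d replicates, %d production frames each",
                    cond, len(production[cond]),
                    production[cond][0].n_frames)

    tables = {cond: _condition_tables(cond, production[cond],
                                      role_maps[cond], config)
              for cond in production}
    conds = list(production)
    rmsf_t = pd.concat([tables[c][0] for c in conds], ignore_index=True)
    com_t = pd.concat([tables[c][1] for c in conds], ignore_index=True)
    sasa_t = pd.concat([tables[c][2] for c in conds], ignore_index=True)
    counts_t = pd.concat([tables[c][3] for c in conds], ignore_index=True)
    edges_t = pd.concat([tables[c][4] for c in conds], ignore_index=True)

    rms2d_all: dict[tuple[str, str, str, str], superpose.Rms2dMatrix] = {}
    div_rows, gap_rows = [], []
    schedules: set[str] = set()
    for cond in conds:
        rms2d_all.update(_rms2d_variants(cond, production[cond],
                                         role_maps[cond]))
    for (cond, rule, variant, schedule) in list(rms2d_all):
        schedules.add(schedule)
    for cond in conds:
        for schedule in sorted(schedules):
            for variant in ("12res", "11res"):
                core_key = (cond, "core", variant, schedule)
                back_key = (cond, "backbone", variant, schedule)
                if core_key not in rms2d_all:
                    continue
                div_core = stats.cross_traj_divergence(rms2d_all[core_key])
                div_back = stats.cross_traj_divergence(rms2d_all[back_key])
                for df, rule in ((div_core, "core"), (div_back, "backbone")):
                    d = df.copy()
                    d["condition"] = cond
                    d["variant"] = variant
                    d["schedule"] = schedule
                    div_rows.append(d)
                gaps = stats.gap_statistics(div_core, div_back, cond)
                gaps["variant"] = variant
                gaps["schedule"] = schedule
                gap_rows.append(gaps)
    divergence_t = pd.concat(div_rows, ignore_index=True)
    gaps_t = pd.concat(gap_rows, ignore_index=True)

    tests_t, boot_t = _inference(conds, rmsf_t, com_t, sasa_t, counts_t,
                                 gaps_t, config)

    metadata = {
        "conditions": {c: len(production[c]) for c in conds},
        "production_frames": {c: int(sum(t.n_frames
                                         for t in production[c]))
                              for c in conds},
        "equilibration_ns": config.equilibration_ns,
        "frame_step_ns": config.frame_step_ns,
        "seed": config.seed,
        "bootstrap_samples": config.bootstrap_samples,
        "bootstrap_method": "centered-pooled-resampling",
        "config_digest": config.digest(),
    }
    return Report(rmsf_t, com_t, sasa_t, counts_t, edges_t, rms2d_all,
                  divergence_t, gaps_t, tests_t, boot_t, metadata)


def _inference(conds, rmsf_t, com_t, sasa_t, counts_t, gaps_t,
               config: RunConfig):
    """Welch/Bonferroni across conditions for each panel + gap bootstraps."""
    c0, c1 = conds
    rows = []

    def groups(df, value, key_col, key):
        sub = df[df[key_col] == key]
        a = sub[(sub["condition"] == c0)][value].to_numpy()
        b = sub[(sub["condition"] == c1)][value].to_numpy()
        return a, b

    m = config.bonferroni
    for role in rmsf_t["role"].unique():
        for rule in ("core", "backbone"):
            sub = rmsf_t[rmsf_t["rule"] == rule]
            a, b = groups(sub, "rmsf_A", "role", role)
            res = stats.welch_test(a, b, m.get("rmsf", 12),
                                   f"rmsf[{rule}]:{role}:{c0}-vs-{c1}")
            rows.append({**res.as_row(), "panel": "rmsf", "rule": rule,
                         "key": role,
                         "mean_A": float(a.mean()), "mean_B": float(b.mean())})
    for pair in com_t["pair"].unique():
        a, b = groups(com_t, "mean_distance_A", "pair", pair)
        res = stats.welch_test(a, b, m.get("com", 4),
                               f"com:{pair}:{c0}-vs-{c1}")
        rows.append({**res.as_row(), "panel": "com", "rule": "core",
                     "key": pair,
                     "mean_A": float(a.mean()), "mean_B": float(b.mean())})
    a = sasa_t[sasa_t["condition"] == c0]["mean_sasa_AB_A2"].to_numpy()
    b = sasa_t[sasa_t["condition"] == c1]["mean_sasa_AB_A2"].to_numpy()
    res = stats.welch_test(a, b, m.get("sasa", 1),
                           f"stripped-sasa:{c0}-vs-{c1}")
    rows.append({**res.as_row(), "panel": "sasa", "rule": "core",
                 "key": "sasa_AB",
                 "mean_A": float(a.mean()), "mean_B": float(b.mean())})
    for role in counts_t["role"].unique():
        a, b = groups(counts_t, "mean_hbonds_per_frame", "role", role)
        res = stats.welch_test(a, b, m.get("hbond", 5),
                               f"hbond:{role}:{c0}-vs-{c1}")
        rows.append({**res.as_row(), "panel": "hbond", "rule": "all",
                     "key": role,
                     "mean_A": float(a.mean()), "mean_B": float(b.mean())})

    boot_rows = []
    for schedule in sorted(gaps_t["schedule"].unique()):
        for variant in ("12res", "11res"):
            sub = gaps_t[(gaps_t["variant"] == variant)
                         & (gaps_t["schedule"] == schedule)]
            ga = sub[sub["condition"] == c0]["gap_A"].to_numpy()
            gb = sub[sub["condition"] == c1]["gap_A"].to_numpy()
            if ga.size < 2 or gb.size < 2:
                continue
            boot = stats.gap_bootstrap(ga, gb, config.bootstrap_samples,
                                       config.seed)
            boot_rows.append({
                "comparison": f"gap[{variant},{schedule}]:{c0}-vs-{c1}",
                "variant": variant, "schedule": schedule,
                "delta_A": boot.observed_delta, "p": boot.p_value,
                "n_boot": boot.n_boot, "seed": boot.seed,
                "method": boot.method,
                "mean_gap_A": float(ga.mean()), "mean_gap_B": float(gb.mean())})
    return pd.DataFrame(rows), pd.DataFrame(boot_rows)


def load_replicate_sets(config: RunConfig) -> dict[str, ReplicateSet]:
    """Build replicate sets from the files named in the config."""
    sets = {}
    for cond, files in config.conditions.items():
        if cond not in config.topologies:
            raise ValueError(f"no topology file for condition {cond!r}")
        topology, _ = read_pdb(config.topologies[cond])
        trajs = [read_trajectory(f, topology,
                                 frame_interval_ns=config.frame_interval_ns)
                 for f in files]
        sets[cond] = ReplicateSet(cond, trajs, config.equilibration_ns)
    return sets


def run_analysis(config: RunConfig,
                 replicate_sets: dict[str, ReplicateSet] | None = None,
                 write: bool = True) -> Report:
    """Load (or accept) the two conditions, run everything, write the report."""
    if replicate_sets is None:
        replicate_sets = load_replicate_sets(config)
    report = analyze_replicates(replicate_sets, config)
    if write:
        report.write(config.output_dir)
    return report
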