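# cartraj

Trajectory analysis of the ribosome **CAR interaction surface** — the
three-residue surface formed by 18S rRNA C1054, A1196 and Rps3 R146 that
hydrogen-bonds the +1 mRNA codon (the codon next in line to enter the A
site) during translocation. R146 can be monomethylated on its guanidinium
group; `cartraj` provides the full measurement pipeline for asking what
that methylation does to CAR: does the guanidinium still stack on A1196,
and does CAR still hydrogen-bond the +1 codon?

The package is aimed at structural bioinformaticians comparing replicate MD
trajectories of the decoding-center neighborhood under two conditions
(methylated mR146 vs unmethylated R146). It implements:

* **Superposition statistics** — least-squares (Kabsch) superposition;
  RMSD time series against a first-frame or iterated-average reference;
  per-residue RMSF about the average structure,
  RMSF_a = √⟨|r_a(t) − r̄_a|²⟩_t, over "core" (base-ring/guanidinium) or
  backbone atom rules; and the pooled pairwise 2D-RMSD matrix across
  replicates (820 frames from twenty 60-ns runs at 1 frame/ns).
* **Stacking readouts** — center-of-mass distances for the stacking chain
  nt35–nt34, nt34–C1054, C1054–A1196, A1196–R146, and the "stripped SASA"
  protocol: solvent-accessible surface area (sphere-point sampling, water
  probe 1.4 Å) of the 4 guanidinium + 9 adenine core heavy atoms, alone
  and together — stacked geometry buries interface area.
* **Hydrogen bonds** — geometric detection (D⋯A ≤ 3.0 Å, D–H⋯A ≥ 135°),
  per-pair occupancy f with the frequency classes f > 0.095 (strong) and
  0.025 < f ≤ 0.095 (weak), and per-residue mean bonds/frame for the +1
  codon and A-site nucleotides against the CAR + anticodon partner set.
* **Replicate-level inference** — the trajectory, not the frame, is the
  unit of replication: Welch t-tests with Bonferroni correction per panel,
  per-trajectory divergence D(e) from the pooled RMS2D matrix, and a
  seeded bootstrap (B = 10,000, centered pooled resampling,
  p = (1 + #{|Δ*| ≥ |Δ|})/(B+1)) on the core-vs-backbone divergence gap.
* **A synthetic-trajectory generator** with per-frame ground truth (two
  presets mirroring the methylated/unmethylated conditions), so the whole
  pipeline is testable with no external data.
* **An onion-shell subsystem builder** — 35 Å sphere selection around a
  center residue with an ~8 Å restrained outer shell, contiguity repair,
  Amber-style restraint-mask output (20 kcal/mol Å²), 5′-phosphate
  stripping and mRNA sequence-edit planning.

See `docs/methods.md` for the model, parameter and design details.

## Worked example

Generate both conditions (eight 60-ns replicates each here; the full study
schedule of 20 × 60 ns + 10 × 100 ns is the default) and run the analysis:

```python
from cartraj import pipeline, synthetic

sets = {}
for i, preset in enumerate(("mR146", "R146")):
    spec = synthetic.preset_spec(preset, replicate_lengths_ns=(60.0,) * 8)
    sets[preset] = synthetic.generate_replicates(spec, seed=10 + i).replicates

config = pipeline.RunConfig(role_map=synthetic.default_role_map_config(),
                            seed=1, bootstrap_samples=2000)
report = pipeline.analyze_replicates(sets, config)

t = report.tests
rows = (((t["panel"] == "rmsf") & (t["key"] == "R146"))
        | ((t["panel"] == "com") & (t["key"] == "A1196-R146"))
        | (t["panel"] == "sasa")
        | ((t["panel"] == "hbond") & (t["key"] == "plus1_C2")))
print(t[rows][["comparison", "mean_A", "mean_B", "p_bonferroni"]]
      .to_string(index=False))
print(report.bootstrap[["comparison", "delta_A", "p"]]
      .to_string(index=False))
```

prints

```
                       comparison     mean_A     mean_B  p_bonferroni
    rmsf[core]:R146:mR146-vs-R146   1.191590   0.800389      0.013795
rmsf[backbone]:R146:mR146-vs-R146   0.251105   0.251186      1.000000
     com:A1196-R146:mR146-vs-R146   4.672292   4.069123      0.000202
      stripped-sasa:mR146-vs-R146 363.200916 342.220247      0.000054
     hbond:plus1_C2:mR146-vs-R146   0.134146   0.314024      0.015021
                   comparison   delta_A      p
gap[12res,40ns]:mR146-vs-R146  0.061877 0.0005
gap[11res,40ns]:mR146-vs-R146 -0.016504 0.0005
```

Reading the table (`mean_A` is the methylated condition): the guanidinium
core RMSF is elevated under methylation (1.19 vs 0.80 Å, Bonferroni
p ≈ 0.014) while its backbone RMSF is indistinguishable; the
A1196–guanidinium center-of-mass distance grows (4.67 vs 4.07 Å) and the
stripped SASA of the pair grows (363 vs 342 Å²) — both signatures of lost
cation-pi stacking; +1 codon C2 hydrogen bonding to CAR drops (0.13 vs
0.31 bonds/frame); and the per-trajectory core-vs-backbone divergence gap
— the primary 12-residue contrast — is larger for the methylated runs
(bootstrap Δ = +0.06 Å, p = 5e-4 at B = 2,000). The 11-residue
((m)R146-excluded) variant is computed alongside but carries little
built-in contrast at this replicate count. On synthetic data these numbers
demonstrate the pipeline's sensitivity to effects built into the
generator, not a biological result.

The same path is available from the shell:

```sh
cartraj simulate --preset both --seed 7 --n-replicates 4 --out data/
cartraj analyze --config data/config.yaml --out report/
cartraj edit-plan AAUGCCUGCUAAC AAUGCCUGCUGCC
cartraj neighborhood --pdb structure.pdb --center A/1054 --radius 35 --shell 8
```

Single-metric subcommands (`rmsf`, `stacking --metric com|sasa`,
`hbonds --metric counts|edges`, `rms2d --rule core --variant 12res`) run
one analysis stage on one condition from the same config file.

`analyze` writes the report as TSV tables (RMSF, COM, SASA, H-bond counts
and classified edges, RMS2D matrices with frame provenance, divergence,
gaps, test results) plus a metadata JSON with seeds and the config digest.

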