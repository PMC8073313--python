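# lipomech

Membrane-lipid mechanics toolkit: how does the fatty-acyl composition of
membrane phospholipids change a muscle cell's response to mechanical stress?

Muscle cells are constantly stretched and relaxed, and their phospholipids
(PLs) — especially phosphatidylcholine (PC) — are unusually rich in
polyunsaturated fatty acids (PUFAs) such as ω-3 docosahexaenoic acid (DHA,
22:6) and ω-6 arachidonic acid (AA, 20:4). Under an osmotic downshock a
myoblast swells, its membrane tension rises, and it either buffers the
excess area by forming vacuole-like dilations (VLDs) or ruptures. PUFA
chains, which can contort and lie down in the bilayer plane, make VLD
formation faster and breakage rarer.

`lipomech` implements the complete computational chain around that question:

1. **Lipidomics profiling** (`lipomech.lipidomics`) — parse `PC x:y` species
   tables or annotate raw MS peak lists by exact mass ([M+H]⁺, ppm
   tolerance), compute the double-bond index
   (DB = 0 / 1 / 2 / >2 percentage split of a lipid class), DHA/AA ratios,
   and a cross-sample PCA of DB indexes.
2. **VLD kinetics and breakage** (`lipomech.vld`, `lipomech.imaging`) —
   normalize per-ROI fluorescence traces to baseline, extract formation
   kinetics (t₀, Vmax, t\_Vmax, plateau), call cell breakage from the
   543 nm channel (relative intensity ≥ 10), bin per-cell VLD counts,
   compute surface-expansion metrics from cross-section areas, and detect
   VLD spots in image stacks (LoG blob detection with backward tracking).
3. **Membrane MD post-processing** (`lipomech.md`) — plan stepwise in-plane
   box extensions, compute acyl-chain tilt-angle and first-to-last-bead
   distance distributions (1-D and joint), area per lipid, and the
   Kirkwood–Irving surface tension
   γ = (L_z/2)·(P_zz − (P_xx+P_yy)/2) from pressure-tensor series, with
   block-averaged errors.
4. **Synthetic data** (`lipomech.synth`) — every input above can be
   generated with known ground truth; condition presets (NT, AA, DHA, plus
   the NT VLD-forming/cracked subpopulations) are calibrated to published
   osmotic-downshock cohort statistics.
5. **Pipeline & CLI** (`lipomech.pipeline`, `lipomech` command) —
   YAML-configured end-to-end runs with bit-reproducible outputs.

## Worked example

Generate a DHA-supplemented cohort of 148 cells, run the full trace
analysis, and summarize:

```python
from lipomech import synth, md
from lipomech.pipeline import analyze_cohort
from lipomech.vld import summarize_condition, bin_vld_counts

params = synth.condition_presets()["DHA"]
cohort = synth.gen_cell_cohort(params, seed=1, n_cells=148)
records = analyze_cohort(cohort)
print(summarize_condition(records, "DHA").to_string(index=False))
```

```
condition             quantity       mean      sem    n
      DHA            vld_count  11.033784 0.553567  148
      DHA                   t0 212.850582 3.222777 1633
      DHA                 vmax   0.023864 0.000301 1633
      DHA               t_vmax 304.095753 3.188182 1633
      DHA              plateau   1.996007 0.014992 1633
      DHA surface_increase_pct  18.856700 1.078740  148
      DHA        t_surface_max 134.594595 5.641736  148
      DHA    breakage_fraction   0.094595 0.024138  148
```

The 148 cells carry 1633 VLDs (11.0 ± 0.6 per cell); the mean time to the
maximal formation rate is t\_Vmax ≈ 304 s after shock with
Vmax ≈ 0.024 s⁻¹, the cell surface peaks ≈ 135 s after shock, and under
10 % of cells break — the fast-forming, breakage-resistant phenotype of
DHA-enriched membranes. Almost half the cells carry more than ten VLDs:

```python
print(bin_vld_counts([r.vld_count for r in records]))
# {'0': 2.70, '1-5': 16.22, '6-10': 33.11, '>10': 47.97}
```

Surface tension from a synthetic pressure-tensor series with a known
5 mN/m target:

```python
series = synth.gen_pressure_series(target_gamma=5.0, lz=10.0, n=10000, seed=1)
res = md.surface_tension(series)
print(f"gamma = {res.gamma:.3f} +/- {res.stderr:.3f} mN/m")
# gamma = 4.917 +/- 0.119 mN/m
```

A 25 % in-plane extension scales a 30 nm box to 37.5 nm per axis and the
membrane area by (1.25)² = 1.5625.

The same analyses are available from the shell, e.g.:

```sh
lipomech synth cohort --preset DHA --seed 1 --truth --out out/
lipomech vld --traces out/traces515.csv --shock-time 50 --out out/ana
lipomech md plan --lx 30 --ly 30
lipomech run --seed 0 --out run_out
```

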