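# fusionscope

Analysis toolkit for in-vitro membrane-fusion assays used to study how small
solutes such as ethanol and methanol modulate SNARE-driven and protein-free
vesicle fusion. It covers five quantitative pipelines, each paired with a
synthetic-data generator that emulates the assay with known ground truth:

1. **Single-vesicle TIRF fusion assay** — movie filtering, per-pixel maximum
   projection, single-particle detection, 5×5-pixel intensity-trace
   extraction, docking/fusion classification, and the per-condition fusion
   probability α = fused / docked with Wilson 95% intervals. A docked vesicle
   is a step in spot fluorescence with no decay; a fusing vesicle shows a
   spike (≈2× the docked plateau, the dequenching burst) followed by rapid
   decay; vesicles that do not fuse within 1 s of docking count as non-fused.
2. **Liposome binding (docking) assay** — first-order kinetic fit
   I(t) = baseline + I_obs(1 − e^{−kt}) of the field-mean intensity sampled
   every 30 s, and the dequenching correction. Fused liposomes are brighter
   by a factor β (observed β = 2), so the observed saturation intensity is
   I_obs = N((1−α)i_lip + αβ i_lip) and normalized binding is recovered as
   N̂ = K·I_obs / (1 + α(β−1)) — at β = 2 a factor 1/(1+α).
3. **sdFLIC microscopy** — a five-layer interference model (bulk Si /
   variable SiO₂ / 4 nm water / 4 nm membrane / bulk water) predicts the
   probed intensity of a dye at height h over the membrane,
   F = |1 + r_ex e^{2ik_ex h}|²·|1 + r_em e^{2ik_em h}|², sampled over 16
   oxide terraces; inversion of a 16-intensity set recovers h, and paired
   condition/control repeats yield distance changes Δd.
4. **Protein-free planar-bilayer fusion assay** — detection of abrupt
   current rises (transient nystatin-channel conductance) in voltage-clamped
   traces, fusion rates in events/min, and normalization of post-alcohol to
   pre-alcohol rates.
5. **Dose and CD utilities** — exact conversions between % v/v, mM and
   % w/v for ethanol/methanol, and aggregation of 8-category CD
   secondary-structure fractions into Helix / Beta / Other-Turn with deltas
   against the 0% alcohol control.

Conditions are compared by one-way ANOVA over per-experiment replicates with
Dunnett-style contrasts against the control.

## Worked example

Simulate a fusion movie at the control condition (3000 frames at 20 ms,
~200 docking events, generator fusion probability 0.34, spot SNR 10) and run
the full analysis chain:

```python
from fusionscope import synthgen, tirf_image, vesicle_events

cfg = synthgen.TirfSimConfig(seed=1)
movie, truth = synthgen.simulate_tirf_movie(cfg)

filtered = tirf_image.moving_average_filter(movie, window=3)
proj = tirf_image.max_projection(filtered)
centers = tirf_image.detect_particles(proj, min_separation=4, threshold_sd=5)
traces = tirf_image.extract_traces(filtered, centers)
events = vesicle_events.classify_traces(traces, cfg.frame_interval)
res = vesicle_events.fusion_probability(events, condition="control")
print(f"{res.n_fused}/{res.n_docked} fused: p = {res.fusion_probability:.3f} "
      f"(95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f})")
```

```
69/200 fused: p = 0.345 (95% CI 0.283-0.413)
```

200 spots were detected and classified as docked; 69 fused within 1 s of
docking, so the estimated fusion probability is 0.345, and the Wilson 95%
interval covers the generator's true value 0.34 (the ground truth of this
movie holds 71 fused of 200 docked). The same pattern works for
the other assays (`simulate_binding_series` → `fit_binding_curve` →
`corrected_binding`; `simulate_flic_sets` → `fit_dye_height`;
`simulate_current_trace` → `detect_fusion_events` → `fusion_rate`).

Every pipeline is also exposed on the command line:

```sh
fusionscope simulate tirf --seed 1 --out sim/
fusionscope detect --movie sim/movie.tif --out traces.csv
fusionscope classify --traces traces.csv --dt 0.02 --out events.csv
fusionscope dose --alcohol ethanol --vv 0.4
```

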