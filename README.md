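# moistnet

Directed-network motif analysis of atmospheric moisture recycling.

Precipitation over land largely originates as evaporation (including plant
transpiration) from other land and ocean regions. Representing gridded
evaporation-to-precipitation flows `m_ij` (moisture evaporated in grid cell
*i* that precipitates in cell *j*) as a directed network makes the structure
of this transport analyzable: which regions act as focused receivers, which
are locked in local feedbacks, and which sit downstream of directed
corridors. `moistnet` implements that pipeline end to end for researchers in
ecohydrology and climate-network analysis:

1. **Backbone extraction.** Flows are ranked by volume and included
   strongest-first until their cumulative volume reaches a fraction ρ of the
   total transport (default ρ = 0.25, sensitivity range 0.20–0.30). The
   result is the unweighted directed backbone with adjacency `a_ij`, built
   for all connections or for land-to-land links only.
2. **Motif census.** Per node, three local structures are counted:
   feed-forward loops (FFL: `A→B, B→C, A→C`, counted at the target `C`),
   zero loops (ZL: `i↔j`, counted per reciprocal partner) and neighboring
   loops (NBr: a ZL `c↔p` fed by an external source `s→c`, counted at the
   center `c`). Counts are max-normalized into motif strengths
   `s_type(i) = n_type(i) / max_j n_type(j)` and compared via the per-node
   differences FFL−ZL and FFL−NBr.
3. **Regional regimes.** Strength differences are averaged over focus
   regions and classified: *directed lens* (FFL−ZL > 0), *washing machine*
   (reciprocity dominates) or *directed corridor* (fed reciprocity
   dominates), with error bars from re-running the pipeline across the ρ
   grid, monthly profiles, and null-model comparisons (density-matched
   random graphs and degree-preserving rewiring).
4. **Desk-scale Lagrangian tracker.** A forward moisture-parcel tracker
   (release ∝ evaporation, advection by interpolated winds, vertical
   redistribution ∝ the column moisture profile, rainout fraction `P/TPW`)
   generates flow fields from first principles on toy atmospheric states.
5. **Synthetic data.** A generator plants lens / washing-machine / corridor
   wiring in labeled blocks over a heavy-tailed random background, so every
   stage is testable against exact ground truth without any data download.

## Worked example

```python
from moistnet import build_backbone, census, motif_strength, sensitivity_over_rho
from moistnet.synthetic import default_regime_spec, generate_regime_flow_field, block_regions

field, truth = generate_regime_flow_field(default_regime_spec(seed=0))
net = build_backbone(field, rho=0.25)
print(net.n_edges, round(net.captured_fraction, 4))   # 764 0.25

cen = census(net)
print(cen.n_ffl, cen.n_zl_pairs, cen.n_nbr)           # 67 53 118

for s in sensitivity_over_rho(field, block_regions(truth)):
    if s.pair == "ffl_minus_zl":
        print(f"{s.region:22s} {s.mean:+.3f} [{s.spread_min:+.3f}, {s.spread_max:+.3f}] {s.label}")
```

```
AB_lens                +0.893 [+0.893, +0.893] directed_lens
CR_washing_machine     -1.000 [-1.000, -1.000] washing_machine
SA_washing_machine     -1.000 [-1.000, -1.000] washing_machine
IA_corridor            -0.120 [-0.120, -0.120] directed_corridor
```

The backbone keeps the 764 strongest links (25.0% of the volume); the
census finds 67 FFLs, 53 reciprocal pairs and 118 NBrs; and the regional
aggregates recover every planted regime with the label stable across the
whole ρ sensitivity grid (the bracketed spread).

The numbered scripts under `analysis/` run the full study line: field
generation, backbone construction, motif census, regional classification
with monthly profiles, null models, and the tracker scenarios. Each writes
its tables to `results/` and prints what it found. The same steps are
available from a shell via the `moistnet` CLI (`synth`, `build`, `census`,
`regions`, `nullmodel`, `track`).

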