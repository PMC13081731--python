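# biodscore

Spatial scoring of immune-cell infiltration in tumor sections, plus the
statistical workflow used around it in preclinical radiation-therapy
studies of syngeneic mouse tumor models.

## The problem

Whole-slide image analysis of an immunostained tumor section yields the
X–Y coordinates (in µm) of every marker-positive cell — typically CD8α⁺
T cells — together with a manually annotated boundary of the viable tumor
tissue. Two tumors with the same overall CD8 density can differ sharply in
*where* those cells sit: infiltrated ("hot") tumors carry effector cells
deep in the core, while immune-excluded tumors pile them up at the margin.
That spatial phenotype matters for therapy response, so it needs a number.

`biodscore` computes the **BioD (biodistribution) score**:

1. Rasterize the viable-tumor polygon (default 4 µm pixels; annotated
   necrotic holes count as outside).
2. Compute each pixel's depth *d* — its Euclidean distance to the nearest
   tumor boundary (exact distance transform).
3. Split the inside pixels into **K = 10 annular zones of equal area**
   using the area quantiles of the depth distribution; zone 1 hugs the
   boundary, zone 10 is the deepest core.
4. Bin zones into **periphery (P)** = zones 1–3, **intermediate (I)** =
   4–7, **core (C)** = 8–10, and compute the average cell density
   (cells/mm²) of each region.
5. Report the pairwise ratios C:P, C:I, I:P. The core-to-periphery ratio
   classifies the phenotype:

   | C:P ratio | label |
   |---|---|
   | > 1 | `core_enriched` (hot, infiltrated) |
   | 0.5 – 1.0 | `homogeneous` |
   | < 0.5 | `excluded` (immune-excluded) |

Around the score, the package implements the companion in vivo / in vitro
statistics: caliper tumor volume V = L·W²/2; tumor growth inhibition
TGI% = 100·(1 − V̄_treated/V̄_control) at the latest day all animals remain
on study, with a one-sided ANCOVA on baseline-adjusted log volumes;
treatment × genotype interaction ANOVA; time-to-event analysis with events
at 1500 mm³, Kaplan–Meier curves and one-sided log-rank tests; 4-parameter
logistic fits of confluency curves with one-sided Hill-slope comparison; a
two-tiered Shapiro–Wilk-gated t-test/Mann–Whitney comparison for
population frequencies; and Spearman correlation of TGI against baseline
infiltration. All p-values are raw (no multiplicity correction), with the
standard star convention (p < 0.05 `*`, < 0.01 `**`, < 0.001 `***`).

A synthetic-data module generates every input the pipeline consumes —
irregular boundaries, depth-profiled point patterns with a one-parameter
enrichment coefficient β (density ∝ exp(β·depth/max-depth)), exponential
caliper growth studies with lognormal noise, and logistic-normal frequency
tables — so the whole analysis is testable end to end without animal data.

## Worked example

```python
from biodscore import (BoundaryGenConfig, PatternConfig, GrowthSimConfig,
                       Zonation, simulate_boundary, simulate_cells,
                       count_by_zone, region_densities, biod,
                       simulate_growth, compute_tgi, derive_events, logrank)

# an irregular 1.5 mm tumor section with a periphery-shifted CD8 pattern
boundary = simulate_boundary(BoundaryGenConfig(seed=1, r0=1500.0, amplitude=0.2))
zn = Zonation(pixel_size=4.0, n_zones=10).fit(boundary)
cells = simulate_cells(zn.zones_, zn.depth_,
                       PatternConfig(seed=1, n_cells=30_000, beta=-5.0))
zc = count_by_zone(zn.zones_, cells)
res = biod(region_densities(zc, zn.zones_))
print(zc.counts.tolist())
print(res.ratio_cp, res.label)

# a 10/group caliper study, treated growth rate roughly halved
study = simulate_growth(GrowthSimConfig(seed=1, n_per_group=10,
    groups={"control": 0.23, "treated": 0.12}, days=tuple(range(0, 22, 3))))
tgi = compute_tgi(study, "treated", "control")
tbl = derive_events(study)            # events at 1500 mm³
p_lr = logrank(tbl, "treated", "control")
```

Output:

```
zone counts: [8628, 6592, 4837, 3412, 2467, 1710, 1122, 673, 389, 170]
ratio_CP=0.061 ratio_CI=0.189 ratio_IP=0.326 label=excluded
TGI = 90.5% at day 21, one-sided ANCOVA p = 6.96e-22
log-rank one-sided p = 0.0000
```

Zone counts fall monotonically from periphery to core — the simulated
β = −5 pattern concentrates at the margin — and the core:periphery ratio
0.061 lands well inside the immune-excluded band (< 0.5). The treated
group's halved growth rate yields ~90% TGI by day 21 and clearly separated
time-to-event curves.

The same pipeline runs from the shell:

```bash
biodscore simulate boundary --seed 1 --out tumor.geojson
biodscore simulate cells --boundary tumor.geojson --beta -5 --out cells.csv
biodscore pipeline --boundary tumor.geojson --cells cells.csv --out results/
```

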