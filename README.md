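# paleofin

Swimming-speed inference for early vertebrates from caudal-fin shape:
phylogenetic regression on living fishes, supertree construction for
Palaeozoic jawless and jawed stem-gnathostomes, and ancestral-state
reconstruction of cruising speed along their phylogeny.

## Who this is for

Palaeobiologists and comparative biologists who want to (a) predict how
fast a fish swims from its body length and the shape of its tail, (b)
propagate such predictions onto fossil taxa whose fins are known only
from flattened lateral reconstructions, and (c) ask whether swimming
capability showed a directional trend across the early evolution of
vertebrates, while carrying phylogenetic and stratigraphic-age
uncertainty through every step.

## The model

**Fin shape.** A caudal fin in lateral view is a closed polygon with the
dorsal and ventral fin-base points marked. Five dimensionless metrics are
measured on it: height-to-width ratio (`HeWiCF`), circularity
`4π·area/perimeter²` (`CircCF`), roundness `4·area/(π·major_axis²)`
(`RoundCF`), solidity `area/convex area` (`SolCF`), and aspect ratio
`height²/area` (`AR`).

**Speed regression (PGLS).** Swimming speed `y` (body lengths per second,
BL/s) over `n` records follows

```
y = X β + ε,   ε ~ MVN(0, σ² C),   C[i,j] = shared root-to-MRCA path (Myr)
```

with candidate designs `X` built from body length, swimming mode
(burst/cruising), swimming condition (free/non-free), locomotion type,
clade, and the fin metrics. Species with several records enter the tree
as randomly resolved zero-length polytomies. Fits are maximum likelihood
(GLS coefficients, ML σ²); 23 candidate models are ranked by AIC and
Akaike weight; collinearity is screened with generalized
variance-inflation factors (threshold `GVIF^(1/(2·Df)) = 2`); predictive
power is checked by leave-one-out cross-validation.

**Supertree pool.** Source topologies from the literature are coded into
a Baum–Ragan binary matrix and combined by matrix representation with
parsimony (random-addition starts, NNI/SPR hill climbing, Fitch
counting). Each supertree is time-calibrated repeatedly by drawing every
fossil tip's age uniformly within its stratigraphic first-appearance
interval, with minimum-age constraints on major clades, giving a pool of
dated trees that expresses both topological and temporal uncertainty.

**Ancestral reconstruction.** Tip speeds (predicted at recorded maximum
body lengths, and size-normalized at 0.1 m total length) are
reconstructed at ancestral nodes by maximum likelihood under Brownian
motion on every tree of the pool. A second, shape-space route
interpolates 102 landmarks around each fin (2 anatomical base points +
100 equal-arc-length semilandmarks), superimposes them by generalized
Procrustes analysis, reconstructs ancestral landmark configurations
coordinate-wise under BM, and feeds the reconstructed shapes back
through the regression.

**Trend test.** On every tree, tip speeds are fitted by Brownian motion
(`x ~ MVN(θ1, σ²C)`, k = 2) and by a drift model
(`x ~ MVN(θ1 + μT, σ²C)` with `T` the root-to-tip depths, k = 3;
identifiable only on non-ultrametric, fossil-tip trees). Models are
compared by `ΔAIC = AIC_BM − AIC_drift`; since BM nests in drift at
`μ = 0`, `ΔAIC ≥ −2` always, and negative values favour BM.

A synthetic-data module generates every input with known ground truth
(record tables, ultrametric extant trees, parametric epicercal /
hypocercal / forked fin outlines, fossil birth–death trees with
stratigraphic ranges and overlapping source topologies), so the entire
chain is testable without any downloaded data.

## Worked example

```python
from paleofin.synthetic_data import SimConfig, simulate_extant_dataset
from paleofin.pgls_speed import select_models, model_table, predict_speed

cfg = SimConfig(seed=42)                       # 61 species, 160 records
records, tree, truth = simulate_extant_dataset(cfg)
fits = select_models(records, tree, seed=1)
print(model_table(fits).head(4).round(3).to_string(index=False))

best = next(f for f in fits if not set(f.formula) & {"LocType", "Group"})
speed = predict_speed(best, {
    "total_length": 10.0,                      # 0.1 m reference body length
    "metrics": {"he_wi": 0.9},                 # hypocercal-grade fin
    "mode": "cruising", "condition": "free",
})
print(f"predicted cruising speed: {speed:.2f} BL/s")
```

prints

```
                                                formula  R2       AIC  dAIC  wAIC
                  Speed ~ Length + Mode + HeWiCF + Cond 1.0 -1298.002 0.000 0.604
          Speed ~ Length + Mode + HeWiCF + Group + Cond 1.0 -1296.514 1.488 0.287
        Speed ~ Length + Mode + LocType + HeWiCF + Cond 1.0 -1293.790 4.212 0.074
Speed ~ Length + Mode + LocType + HeWiCF + Group + Cond 1.0 -1292.301 5.701 0.035
predicted cruising speed: 3.88 BL/s
```

Model selection recovers the generating design (length + mode +
height-to-width ratio + condition) with the highest Akaike weight, and
the prediction applies that model to a new fin: a 10 cm free-swimming
cruiser with a low tail (`he_wi = 0.9`) is predicted to cruise at about
3.9 body lengths per second. On noise-free synthetic data the regression
explains the records essentially exactly (R² ≈ 1); on empirical
compilations it will not.

The full chain (fossil predictions → calibrated pool → both ASR routes →
trend models) is driven by `paleofin.pipeline.run_pipeline` or the CLI:

```
paleofin simulate extant --seed 3 --out sim/extant
paleofin simulate fossil --seed 3 --out sim/fossil
paleofin fit --records sim/extant/records.csv --tree sim/extant/extant_tree.nwk
paleofin run --config pipeline.yaml
```

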