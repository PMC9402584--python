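# Data dictionary

All tables are UTF-8 CSV, '.' decimal separator, long format. Trees are
Newick; tree pools are one Newick string per line. Landmarks use TPS
blocks (`LM=`, coordinate rows, `ID=`).

## records.csv — extant swimming-speed records

| column  | type  | units | meaning |
|---------|-------|-------|---------|
| species | str   |       | species label; must match a tip of the extant tree |
| speed   | float | BL/s  | recorded swimming speed (response) |
| Length  | float | cm    | total body length for this record |
| Mode    | str   |       | `burst` or `cruising` |
| Cond    | str   |       | `free` or `non-free` (controlled conditions) |
| LocType | str   |       | `anguilliform`, `carangiform`, `median/paired fin`, `thunniform` |
| Group   | str   |       | `chondrichthyan` or `osteichthyan` |
| HeWiCF  | float | —     | caudal-fin height-to-width ratio |
| CircCF  | float | —     | circularity, 4π·area/perimeter² |
| RoundCF | float | —     | roundness, 4·area/(π·major_axis²) |
| SolCF   | float | —     | solidity, area/convex area |
| AR      | float | —     | aspect ratio, height²/area |

Several rows may share a `species` (repeated records).

## Outline CSV (one file per taxon, `<taxon>.csv`)

Header comment `# dorsal_base=<i> ventral_base=<j>` (vertex indices of
the two fin-base landmarks), then `x,y` rows: ordered polygon vertices,
y-axis up, anterior left; the closing edge is implicit.

## ranges.csv — stratigraphic tip ranges

`taxon,oldest,youngest` — first-appearance interval bounds in Ma,
`oldest >= youngest > 0`.

## constraints.csv — node minimum ages

`clade,min_age` — `clade` is a `;`-joined taxon set; `min_age` in Ma
applies to the MRCA when the set is monophyletic.

## lengths.csv — fossil body sizes

`taxon,max_length_cm` — maximum total body length per fossil taxon.

## clades.json

`{"<clade name>": ["taxonA", "taxonB", ...], ...}` — named taxon sets
used for per-clade ancestral summaries.

## Length-conversion table

`species,kind,slope,intercept` with `kind` in
`standard->total | fork->total`; `total_cm = slope*measured_cm + intercept`.

## Pipeline outputs (in `out_dir/`)

- `model_selection.csv` — formula, R2, AIC, dAIC, wAIC per candidate.
- `gvif.csv` — term, Df, GVIF, GVIF^(1/(2Df)), flagged.
- `loo_predictions.csv` — species, observed, predicted speeds.
- `fossil_tip_speeds.csv` — taxon, speed_raw (at max length),
  speed_normalized (at the reference length).
- `pool.nwk` — calibrated supertree pool, one Newick per line.
- `asr_{raw,normalized}_summary.csv` — clade, n_trees, mean, sd of
  ancestral speed estimates across the pool.
- `asr_shape_summary.csv` — same for the shape route (subsampled trees).
- `mean_ancestral_shapes.tps` — coordinate-wise mean ancestral
  configurations per clade.
- `evomodels_{raw,normalized}.csv` — per-tree BM/drift parameters, logL,
  AIC, dAIC (= AIC_BM − AIC_drift), equally_supported flag.
- `evomodels_summary.json` — mean ± SD of parameters and dAIC.
- `manifest.json` — seeds, settings, chosen models, SHA-256 of outputs.
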