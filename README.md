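# rangeshift

Climate-change range projection for species assemblages: bioclimatic
covariates from monthly climate, maximum-entropy species distribution
models, circulation-model ensemble projection, dispersal-constrained range
forecasting, and assemblage richness summaries — with a synthetic-data
module that makes the whole pipeline testable against known ground truth.

The package is aimed at ecologists and biodiversity-informatics developers
who want a transparent, fully inspectable implementation of the standard
presence-background projection workflow: fit a climatic niche model per
species on a baseline climate, project it across an ensemble of future
climate realizations, decide which newly suitable areas each species can
actually reach, and summarize what the assemblage gains and loses.

## The model

For each species, suitability is modelled by the maximum-entropy Gibbs
distribution over background cells

    P(x) ∝ exp(λ · f(x)),

where the features *f* are linear, quadratic and pairwise-product terms of
six bioclimatic covariates (annual mean temperature, temperature
seasonality, temperature of the warmest period, annual precipitation,
precipitation seasonality, precipitation of the driest period), and λ
maximizes the L1-penalized log-likelihood of the presence records

    ℓ(λ) = mean_presences λ·f(x) − log Σ_background e^{λ·f(x)} − Σ_j β_j |λ_j|.

The raw distribution is rescaled to a logistic suitability index in (0, 1)
using the fitted distribution's entropy *H*, thresholded by the
entropy-equating rule (keep the k ≈ e^H best cells), projected onto each
(GCM, realization, decade) future surface, and summarized per decade by the
realization-weighted ensemble mean and extremes. Future binary ranges are
constrained by full, rate-limited (3 km/yr buffers) or no-dispersal
scenarios, plus a per-species "realistic" selection among them. The model
class follows the scikit-learn estimator contract (`MaxentSDM().fit(X, y)`,
`predict_proba`, `get_params`), so it composes with sklearn tooling.

See `docs/methods.md` for the full model description, parameter defaults
and numerical choices.

## Worked example

Run the bundled synthetic scenario (a 60 × 80 grid of 5-km cells, 4 GCMs
with 8 realizations, 10 decades 1990–2080, 12 virtual species with known
Gaussian niches):

```python
import rangeshift as rs

config = rs.default_scenario(seed=1)
manifest = rs.run(config, "runs/demo")   # ~10 s; 1085 artifacts
```

or from the shell: `rangeshift run --seed 1 --out runs/demo`.

`runs/demo/results/model_evaluation.csv` reports the per-species fit — with
this seed, training AUC ranges from 0.919 to 0.955, so all 12 species pass
the AUC ≥ 0.7 screen. `change_records.csv` holds the per-species range
change between 1990 and 2080; the first rows under the realistic scenario:

```
species_id  scenario  area_1990_km2  area_2080_km2  proportion_of_current direction
      sp01 realistic        25050.0        25025.0                   1.00 No change
      sp02 realistic        33750.0        37000.0                   1.10  Increase
      sp03 realistic        23600.0        29700.0                   1.26  Increase
      sp04 realistic        26150.0        27925.0                   1.07  Increase
```

`proportion_of_current` is the 2080 range area as a fraction of the current
(realized) range, rounded to two decimals before classification — a species
at exactly 1.00 reads "No change". `assemblage_summary.csv` aggregates the
directions per dispersal scenario:

```
    scenario  n_increase  n_decrease  n_no_change  mean_pct_shift
        full          11           0            1          138.17
rate_limited          11           0            1          138.17
        none           0           9            3          -42.75
   realistic          10           1            1          113.58
```

Under no dispersal a range can only shrink (mean −42.75% here), while free
tracking of the shifting climate lets most of these virtual species grow —
the spread between the rows is exactly the sensitivity to the dispersal
assumption the pipeline is built to expose. `group_comparison.csv` adds
one-way ANOVAs of proportional change across movement classes and
biogeographic groups (F = 0.54, p = 0.71 and F = 1.32, p = 0.35 with this
seed), and `results/richness_*.tif` hold the stacked richness maps and
their 1990→2080 change per scenario.

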