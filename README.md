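# bearsurv

Abundance estimators for aerial line-transect surveys of brown bears
(*Ursus arctos*), built around the double-observer protocol used in
southwestern Alaska: a pilot and an observer independently search one side
of a fixed-wing aircraft, perpendicular distances and group sizes are
recorded, and each detection carries a capture history (pilot only,
observer only, or both).

Aerial bear detections are *humped* in distance — detection peaks at an
apex c off the line because the strip underneath the aircraft is hard to
see — which breaks the standard distance-sampling assumption of certain
detection on the line. The package implements three estimators that deal
with this in different ways, plus a ground-truthed synthetic-survey
generator for validating all of them:

* **MRDS baseline** (`bearsurv.mrds`) — a two-piece normal detection shape
  g(x) = exp(−(x−c)²/2σ₁²) for x ≤ c (σ₂ beyond), with *point
  independence*: the observers are treated as independent only at the apex,
  where the intercept-only mark–recapture model supplies the absolute joint
  detection probability p· = 1 − (1−p₁)(1−p₂). Abundance is
  Horvitz–Thompson, N̂ = Σ sᵢ/(p̂·ĝ(xᵢ)), scaled by study area over covered
  area; uncertainty via a transect bootstrap.
* **Bayesian CDS** (`bearsurv.cds`) — left-truncate at the fitted apex so
  distances decline monotonically, discard the capture histories, and fit a
  half-normal detection model by data augmentation: z ~ Bern(ψ),
  x ~ U(0, w′), group size 1 + Poisson(λ), detection exp(−x²/2σ²).
  Optionally an informed lognormal prior on σ carries detection information
  over from a data-rich survey, which substantially tightens abundance
  posteriors on sparse (~60-detection) surveys.
* **Open-distance availability model** (`bearsurv.open_distance`) — on
  multi-day surveys whose daily transects each represent the study area,
  day-varying availability φ_t ~ Beta(α, β) thins a shared superpopulation
  (temporary emigration). Estimates mean availability p̄_a and the
  superpopulation N_super; the closed estimators above track only
  p̄_a × N_super.

## Worked example

```python
import bearsurv as bs
from bearsurv.scenarios import mrds_recovery_world

dataset, record = bs.simulate_survey(mrds_recovery_world(seed=7))
fit = bs.fit_mrds(dataset)
est = bs.bootstrap_mrds(dataset, B=200, seed=7)
print(fit.curve.apex_c, fit.p_dot, est.n_hat, (est.lo, est.hi), est.cv)
```

prints (seed 7):

```
311 m apex   p. = 0.986   N_hat = 1893   CI (1606, 2201)   CV 0.08
```

i.e. the fitted detection curve peaks 311 m off the line (truth 300 m), the
joint probability of at least one observer detecting a group at the apex is
0.986, and the Horvitz–Thompson estimate is 1,893 bears with a bootstrap
95% CI of (1,606, 2,201) against a true abundance of 2,000. The
`examples/` directory has one short script per capability: simulation, the
MRDS baseline, apex-truncated CDS, informed priors, availability /
superpopulation estimation, and the cross-estimator comparison table with
the detection-fit plot.

Real surveys are read from two CSV files (`transects.csv`:
`transect_id,date,length_km`; `detections.csv`:
`transect_id,distance_m,group_size,history` with history ∈ {P,O,B}) via
`bs.read_survey`, with the truncation distance and study area supplied in a
YAML/JSON config.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on freshly simulated surveys: the
MRDS baseline with bootstrap CI, CDS on the apex-left-truncated data, the
informed-prior transfer from a data-rich donor survey to a sparse one, and
the six-day open-distance availability fit, printing each estimate against
the generating truth and the comparison table, and writes the results JSON
to `--out`. All randomness derives from `--seed`.
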