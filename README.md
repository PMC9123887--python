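# whistlegam

Passive-acoustic presence modelling for coastal dolphins, from raw whistle
detection logs to hierarchical generalized additive models.

Bottlenose dolphins in subtropical lagoons are monitored by mooring
hydrophones for a day or two at a time and screening the recordings for
whistles.  The analysis question is *when* the animals use the lagoon: do
detections follow the hour of day, the tide, the moon cycle, the seasonal
temperature cycle — and do those rhythms themselves change between seasons?
`whistlegam` implements that full analysis chain for ecologists working
with detection-positive interval data:

1. **Ingestion** — whistle events are pooled into clock-aligned 10-min bins;
   each monitored hour is scored by its number of detection-positive bins
   (dp10m h⁻¹ ∈ {0…6}), the modelling unit, together with recording effort.
2. **Covariates** — moon-cycle fraction (0 = new, 0.5 = full), tidal height,
   its 60-min change and the curvature trend of a trailing 3-h cubic fit,
   hour of day, civil daylength, daily SST / ΔSST / chlorophyll, and static
   site descriptors; plus a Spearman collinearity screen (|ρ| > 0.7) and the
   Kaiser–Meyer–Olkin sampling-adequacy measure.
3. **Circular statistics** — the Hermans–Rasson uniformity test with
   Monte-Carlo p-values (robust to multimodal detection rhythms) and
   CircSiZer-style maps of significantly rising/falling detection intensity
   across von Mises kernel bandwidths.
4. **GAM engine** — penalized Poisson regression with log link,

   log λₜ = β₀ + s(moon) + s(hour) + s(SST) + s(depth) + s(distance)
            + te(∂tide, tide) + β·effortₜ,

   built on cyclic and natural cubic regression splines (exact ∫f″²
   penalties), low-rank thin-plate splines and tensor products; penalized
   IRLS with REML (or GCV) smoothing selection; AIC/AIC-weight forward
   selection; and an exclusion-based decomposition of explained deviance.
5. **Grouped (hierarchical) models** — for a candidate variable and a
   cluster factor, the nested family G / S / I / GS / GI varies how much
   freedom each cluster's smooth gets (shared vs individual penalties, with
   or without a global smooth; the GI global smooth is penalized on its
   squared first derivative).  Pairwise smooth differences with pointwise
   95% CIs are computed by the zeroed-prediction-matrix contrast
   X_new β̂ ± z·√diag(X_new V̂β X_newᵀ).
6. **Clustering** — deployments grouped by environment via HCPC
   (KMO-screened PCA → Ward dendrogram → k-means consolidation) and compared
   with tie-corrected Kruskal–Wallis and Nemenyi all-pairs rank tests.
7. **Synthetic study generator** — a generative twin (mixed semidiurnal
   tide, synodic moon, seasonal SST, Poisson dp10m with cluster-varying diel
   amplitude) so the entire pipeline is testable offline and parameter
   recovery can be scored against known truth.

## Worked example

```python
import whistlegam as wg
from whistlegam.pipeline import global_model_spec

schedule, forcings, truth, records = wg.simulate_study(seed=1)
frame = wg.records_to_frame(records)
fit = wg.fit(global_model_spec(frame, {}), frame)
print(fit.deviance_explained, fit.aic)
```

Running `python examples/05_global_gam.py` prints:

```
n = 663 hours, deviance explained = 0.430, AIC = 1602.7
term                 edf           p   dev share
effort_min          1.00    1.41e-04        4.3%
s(moon)             3.50    7.18e-21       26.8%
s(hour)             4.71    2.00e-26       32.3%
s(sst)              3.79    4.82e-29       40.5%
...
```

SST carries the largest deviance share and hour the second: temperature
(a proxy for seasonal prey availability) structures detections most, with a
strong diel rhythm on top.  `examples/07_grouped_models_contrast.py` then
shows the grouped variants beating the global model (δAIC −12.1 for S,
−5.8 for I) and localizes *when* the May–Jul and Oct–Mar daily patterns
differ:

```
May-Jul vs Oct-Mar hour-smooth difference (variant S):
  significantly different between 01.2 h and 08.6 h
  significantly different between 15.7 h and 19.9 h
```

Each script in `examples/` demonstrates one capability and prints a line on
what its numbers mean.  The same analysis runs from a shell via the thin
CLI: `whistlegam run-all --seed 1 --outdir out` (stages communicate through
CSV/JSON files, so `whistlegam gam --outdir out` re-runs a single stage).

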