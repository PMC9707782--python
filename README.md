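# beartrack

Camera-trap analysis of large-carnivore habitat use along an urban–wildland
gradient, built around the Sooke (Vancouver Island) black bear study design:
54 camera traps in three disturbance strata (11 urban, 19 rural, 24 wild)
monitored over 13 months. The package is for ecologists who want a tested,
reusable implementation of the full analysis chain — from raw detection
records to model selection and diel-shift inference — together with a
synthetic-study generator so every stage can be validated without field data.

## What it computes

**Detection events.** Raw records at a site are collapsed into independent
detection events separated by ≥ 30 minutes, classified diurnal/nocturnal
from site-specific sunrise and sunset (NOAA solar geometry, −0.833° rise/set
altitude), and aggregated into a site × month count table with active
camera-days as sampling effort.

**Habitat-use model.** Monthly counts y_ij at site i follow a zero-inflated
negative binomial mixed model:

    y_ij ~ π·δ₀ + (1−π)·NB(μ_ij, dispersion)
    log μ_ij = x_ij'β + u_i + log(effort_ij),   u_i ~ N(0, σ²)

with either NB1 (Var = μ(1+α)) or NB2 (Var = μ(1+μ/θ)) variance, an
intercept-only zero-inflation component, and a site random intercept. The
marginal likelihood integrates u_i out by adaptive Gauss–Hermite quadrature.
Candidate models (conflict / anthropogenic / environmental / full /
seasonal-conflict hypotheses) are compared by AICc and Akaike weights,
with covariates standardized, screened for collinearity (|r| ≥ 0.7), and
extracted from rasters as 150 m area-weighted disc buffers (500 m for
conflict-report counts). Moran's I on per-site residuals checks for
residual spatial autocorrelation.

**Nocturnality.** The diel shift in disturbed strata is the log risk ratio
RR = ln(X_h/X_l) of nocturnal proportions (high- vs low-disturbance), with

    Var(RR) = 1/O_high,night − 1/O_high + 1/O_low,night − 1/O_low

a Wald 95% CI, and a randomization null built by re-assigning detections to
strata 1000 times (preserving stratum totals and diel labels). A shift is
significant when the observed CI and the null's 95% highest-density
interval do not overlap.

## Worked example

The published day/night detection splits of the Sooke study are bundled
(`beartrack.study`); the full nocturnality inference from them:

```python
import pandas as pd
from beartrack import study
from beartrack.diel import nocturnality_analysis

rows = []
for stratum in ("urban", "rural", "wild"):
    o, n_night = study.STRATA_DETECTIONS[stratum], study.NIGHT_DETECTIONS[stratum]
    rows += [{"stratum": stratum, "diel": "night"}] * n_night
    rows += [{"stratum": stratum, "diel": "day"}] * (o - n_night)
res = nocturnality_analysis(pd.DataFrame(rows), n_boot=1000, seed=7)
```

which prints

```
class   o  o_night     x    rr  ci_low  ci_high  hpdi_low  hpdi_high  significant
urban  77       40 0.519 0.844   0.425    1.264    -0.351      0.320         True
rural 368      173 0.470 0.744   0.368    1.121    -0.234      0.285         True
```

Bears in urban areas were roughly half nocturnal (X = 0.52) against 0.22 at
wild sites, a log risk ratio of 0.84 (95% CI 0.42–1.26) that falls far
outside the randomization null (HPDI −0.35 to 0.32): a significant shift
toward nighttime activity near people, and likewise for rural sites.

A complete synthetic study and a model fit:

```python
from beartrack.simulate import generate_study
from beartrack.covariates import standardize
from beartrack.zinb import fit

bundle = generate_study(seed=7)             # 54 sites x 13 months
data, _ = standardize(bundle.site_month.copy(), columns=["EVI"])
res = fit(bundle.truth.model_spec(), data, seed=0)
```

yields 702 site-month rows with an 80% zero fraction and 624 simulated
detections, and the fit recovers the generating coefficients (vegetation
index effect 0.57 ± 0.13, urban 2.22 ± 0.51 and rural 2.38 ± 0.43 relative
to wild, σ_site = 1.00) within their standard errors of the truth.

The same pipeline runs from a shell:

```bash
beartrack simulate --seed 7 --out run/
beartrack events --detections run/detections.csv --deployments run/deployments.csv --out run/
beartrack nocturnality --events run/events.csv --out run/
beartrack all --seed 7 --out run_all/        # everything incl. model selection
```

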