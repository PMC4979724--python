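# clinezone

Spatiotemporal hybrid-zone analysis for diploid microsatellite data.

`clinezone` re-implements, as a tested and reusable Python package, the
analysis pipeline used to ask whether a hybrid zone has moved or changed
shape between two sampling eras. It was built around the contact zone
between the chorus frogs *Pseudacris fouquettei* and *P. nigrita* across
the Pearl River (south-eastern USA), which was surveyed with the same
microsatellite markers in 1976 ("historical") and 2001–2012 ("recent"),
and it ships the published population-level summaries of that system so
the cline analyses can be re-run end to end.

The package is aimed at population geneticists working with multi-era or
multi-transect hybrid-zone samples: it covers data import and spatial
pooling of collection sites, per-population diversity statistics,
maximum-likelihood hybrid indices, projection onto a one-dimensional
transect, Szymura–Barton geographic cline fitting with MCMC credibility
intervals and AIC model selection, reciprocal constraint tests between
eras, stratified subsampling, and a synthetic-data generator with known
truth for validation.

## The model

Each individual receives a hybrid index *h* ∈ [0, 1] by maximum
likelihood. Treating every allele copy *a* as an independent draw from a
mixture of the two parental pools (reference at *h* = 0, alternative at
*h* = 1),

    ln L(h) = Σ ln[ h·f_alt(a) + (1 − h)·f_ref(a) ],

with a 95% profile-likelihood interval {h : ln L(h) ≥ ln L(ĥ) − 1.92}.

Per-population mean hybrid indices p̄ᵢ are then modelled along the
transect position *x* (km) with the Szymura–Barton sigmoid cline

    s(x) = 1 / (1 + exp(−4 (x − c) / w)),

where *c* is the cline center and *w* the width (inverse of the maximum
slope). Optional exponential tails, each governed by a distance δ from the
center and a slope ratio τ ∈ [0, 1], produce the "stepped" cline shape;
five model variants (no tails; west; east; symmetric; asymmetric) are
compared by AIC = 2k − 2 ln L. The fit maximises the binomial
log-likelihood ratio against the saturated model,

    ln L = Σᵢ Nᵢ [ p̄ᵢ ln(μᵢ/p̄ᵢ) + (1 − p̄ᵢ) ln((1 − μᵢ)/(1 − p̄ᵢ)) ],

so a perfect fit gives ln L = 0. Parameter uncertainty comes from
covariance-tuned Metropolis MCMC (three chains; 95% credibility intervals
are posterior 2.5–97.5 percentiles), and temporal change is tested by
refitting one era with its center and/or width constrained to the other
era's credibility interval (likelihood ratios and AIC), and by stratified
subsampling with matched sample sizes.

## Worked example

```python
import clinezone as cz
from clinezone import datasets

# seven 1976 populations: transect position, mean hybrid index, N
data = datasets.historical_cline_data()
spec = cz.ClineModelSpec(tails="none", orientation="decreasing")

fit = cz.fit_cline_mcmc(
    data, spec,
    settings=cz.MCMCSettings(burnin=5_000, generations=50_000,
                             thin=10, chains=3, seed=2),
)
print(f"center {fit.params.center:.3f} km, width {fit.params.width:.3f} km")
print(f"lnL {fit.lnl_max:.4f}, AIC {fit.aic:.4f}")
print("center 95% CrI", tuple(round(v, 1) for v in fit.cri["center"]))
print("width  95% CrI", tuple(round(v, 1) for v in fit.cri["width"]))
```

prints

```
center 257.532 km, width 13.947 km
lnL -3.8935, AIC 11.7870
center 95% CrI (255.3, 259.9)
width  95% CrI (10.3, 25.8)
```

i.e. the historical cline is centred at ~257.5 km along the transect and
is ~14 km wide — a narrow transition. Refitting the recent data the same
way gives a centre of ~230 km with a width of ~350 km: the center is
statistically indistinguishable between eras while the width increased by
an order of magnitude, which is the package's headline reproduction.

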