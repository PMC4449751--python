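# ibrkit

Isolation-by-resistance landscape genetics in Python: parameterize landscape
resistance surfaces, compute circuit-theory pairwise effective resistance
between focal groups, relate it to microsatellite genetic differentiation
with MLPE linear mixed models, select surfaces and models by a
four-criterion consensus rank, and build coefficient-weighted combined
resistance surfaces.

The package is for landscape geneticists asking which landscape features —
habitat cover, terrain, roads, seasonal habitat suitability — shape gene
flow across a region, and at what spatial scale. It implements the full
group-based workflow for species sampled at communal sites (the motivating
system is a lekking grouse sampled at leks across a state-sized extent), and
ships a synthetic-data module so the entire pipeline runs, and is tested,
without any external rasters or genotypes.

## The model

For groups $i < j$ with pairwise genetic distance $y_{ij}$ (Nei's $G_{ST}$
or Jost's $D_{est}$) and pairwise effective resistances $z_{ij,k}$
(standardized to twice their SD), the MLPE mixed model is

$$y_{ij} = \beta_0 + \sum_k \beta_k z_{ij,k} + u_i + u_j + \varepsilon_{ij},
\qquad u \sim N(0, \sigma_u^2 I_G),\ \varepsilon \sim N(0, \sigma_e^2 I),$$

so rows sharing a group covary by $\sigma_u^2$ — the correction for the
non-independence of pairwise data. Fits are by REML (profiled restricted
likelihood over the variance ratio) and by a conjugate Gibbs sampler; the
two agree closely on identifiable data.

Upstream, each covariate raster becomes a family of 15 candidate resistance
surfaces: five parameterizations — untransformed, and the exponential
transformations $f(R) = e^{\alpha R / R_{\max}}$ (emphasizing
high-resistance habitat) and its reversal-based converse (emphasizing
favourable habitat), each at $\alpha \in \{5, 10\}$ — crossed with circular
focal-mean windows of 1.5, 6.44 and 17.33 km radius that set the
operational scale. Distance-decay road surfaces $e^{-d/\alpha}$
($\alpha = 0.564$ km) skip the windows (5 variants). Pairwise resistance is
the effective resistance of the raster-as-resistor-network: cells are nodes,
neighbouring cells are joined by resistors averaging the two cell values
($\times\sqrt2$ diagonally), and $R_{\mathrm{eff}}(s,t) =
(e_s-e_t)^\top L^+ (e_s-e_t)$ for the graph Laplacian $L$.

Because no single criterion is trustworthy here (REML information criteria
are contested; the F-based marginal $R^2$ prefers complex models), candidate
models are ranked separately by AICc, DIC, $R^2_\beta$ and $R^2_m$ and
compared by the mean and SD of their four ranks.

## Worked example

`examples/05_mlpe_fit.py` simulates pairwise distances over 25 groups with a
true slope of 0.5 on a circuit-resistance predictor and fits both ways:

```
300 pairwise rows over 25 groups (true slope 0.5, sigma_u 0.2, sigma_e 0.1)

REML:  slope = 0.4883  [0.4523, 0.5242]
       sigma_u^2 = 0.0409, sigma_e^2 = 0.0095
MCMC:  slope = 0.4882  [0.4518, 0.5243]  (chains agree: True)

criteria: AICc = -415.61, DIC = -519.29, R2_beta = 0.715, R2_m = 0.542
```

The REML and posterior-mean slopes agree to four decimals and bracket the
truth; the four criteria feed the consensus rank used in model selection.
`examples/06_model_selection.py` continues the pipeline: the surface variant
the data were generated from (high-10 transformation, 1.5-km window) wins
the 15-variant univariate screen with mean rank 1.00, and the
undifferentiated null ranks last in the model set. The other examples cover
landscape simulation, diversity statistics, surface families, circuit
distances, and combined surfaces.

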