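# sembpp — model plausibility for structural equation models

How plausible is a structural equation model, *compared to the models it
could easily have been*?  Conventional fit indices (CFI, RMSEA, SRMR)
measure how well one model reproduces the sample covariance matrix, but
they cannot say how much more the data support that model than a nearly
identical alternative — and all of them crown the saturated model.
`sembpp` answers the comparative question with **Bayesian posterior model
probabilities (BPP)** over an automatically generated set of *neighboring
models*, for researchers in psychology, epidemiology and the social and
health sciences who fit path-analysis and confirmatory-factor models.

## The statistic

For candidate models $M_1,\dots,M_m$ with BIC scores $\mathrm{BIC}_i$ and
prior probabilities $\mathrm{Prior}(M_i)$,

$$
\mathrm{Posterior}(M_i)
 = \frac{e^{-\tfrac12(\mathrm{BIC}_i-\mathrm{BIC}_1)}\,\mathrm{Prior}(M_i)}{D},
\qquad
D = \sum_{j=1}^{m} e^{-\tfrac12(\mathrm{BIC}_j-\mathrm{BIC}_1)}\,\mathrm{Prior}(M_j),
$$

with an arbitrary reference model $M_1$ (the choice cancels).  The BIC is
computed from the model $\chi^2$ as $\chi^2 + q\ln N$, where
$q = p(p+1)/2 - df$ is the free-parameter count.  Posteriors sum to one
and, under equal ("unbiased") priors $1/m$, rank models exactly as BIC
does — but on the interpretable scale of probability.

The candidate set is built automatically: every model that differs from
the hypothesized model by freeing one fixed parameter (the $-1\,df$ set)
or fixing one free parameter to zero (the $+1\,df$ set), optionally out to
a wider df radius.  Added paths may not create feedback loops; covariances
between causally ordered variables (or their error terms) are excluded by
default, as are indicator error covariances in latent-variable models.
Empirically equivalent candidates — same df, same $\chi^2$, same implied
covariance matrix — are collapsed to a single representative.

A prior-sensitivity analysis reports the minimum prior the hypothesized
model would need for its posterior to reach a target value, and helper
schemes construct modestly informative priors ($p_1 = 1/(0.80m + 0.20)$
for one favored model, $p_1 = 1/(0.80k + 0.20k_1)$ for $k_1$ favored
models among $k$).

## Worked example

Simulate a dataset (n = 200) from the shipped serial-parallel mediation
analog (x → m11 → m12 → y and x → m2 → y), then run the whole workflow —
parse, fit, enumerate neighbors, fit them, compute BPPs — in one command:

```sh
sembpp simulate --analog serial_parallel --n 200 --seed 42 --out data.csv
cat > model.txt <<'EOF'
m11 ~ x
m12 ~ m11
m2 ~ x
y ~ m12 + m2
EOF
sembpp modelset --model model.txt --data data.csv --bpp-target 0.8
```

Output (abridged):

```
        model sep  df_diff  df  chisq     p  Prior     BIC   BPP   CFI  RMSEA  SRMR
     original   |        0   5  6.285 0.279  0.077  59.268 0.457 0.994  0.036 0.035
   add: y m11   |        1   4  2.005 0.735  0.077  60.286 0.275 1.000  0.000 0.026
  add: m12 m2   |        1   4  5.066 0.281  0.077  63.348 0.059 0.995  0.037 0.028
  ...
  drop: m11 x   |       -1   6 89.942 0.000  0.077 137.627 0.000 0.632  0.265 0.193

minimum prior for 'original' to reach BPP 0.800: 0.283
```

Thirteen models survive after collapsing an equivalent cluster (the three
ways of connecting m11 and m2 fit identically), so the unbiased prior is
1/13 ≈ .077.  The hypothesized model is the most plausible (BPP .457) but
not unambiguously so: the model adding the path m11 → y retains BPP .275,
and a prior of .283 on the original would be needed for a posterior of
.80.  Note that CFI/RMSEA/SRMR prefer the *added-path* model — they
cannot weigh parsimony against fit the way the posterior does.

BPPs can also be computed without raw data, from a published covariance
matrix (`--cov cov.csv --n 200`) or directly from a table of BICs:

```sh
sembpp bpp-table --bics bics.csv          # columns: model,bic[,prior]
```

The same functionality is available as a library
(`parse_model`, `fit_ml`, `generate_model_set`, `compute_bpp`,
`min_prior_for_target`, `combine_model_sets`, `build_graph`/`export_dot`
for the BPP-scaled model-network graph).

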