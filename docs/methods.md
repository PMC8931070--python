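# Methods

## The cascade model

The simulation operates on a weighted directed graph G = (V, E, W) whose
nodes are countries and whose weights W_ij are annual calorie flows from
exporter i to importer j. Three country attributes enter the dynamics:
GDP (only relative values matter), population (unit conversion only) and
domestic food supply (kcal/year). Production is not an input; it is
derived as supply plus the net trade balance, which makes baseline demand
identically equal to supply and anchors the accounting.

A run perturbs a single origin: its production drops by a fraction
`shock_fraction` (default 0.30, the reference experimental condition).
The origin offsets a share α of the loss by cutting exports and 1 − α by
raising imports:

* **Import side (t = 1 only).** Each inbound edge grows pro-rata to its
  baseline share of the origin's imports. Suppliers are assumed to honor
  the extra demand without capacity limits and thereby acquire the
  corresponding deficit themselves. If the origin has no baseline imports
  and α < 1, the import share is rerouted through the export channel
  (logged as a warning); whatever exceeds total exports stays with the
  origin. This keeps conservation exact in every degenerate case.
* **Export side.** A country with deficit dd cuts each positive out-edge
  by dd · F_ij, where F_ij is the GDP-inverse rationing share
  ((S − GDP_j)/S · 1/(k−1) over the k current positive out-partners with
  GDP sum S; F = 1 for a sole partner). Shares always sum to one and are
  anti-monotone in partner GDP: poorer partners absorb more. Cuts
  truncate at zero weight; a truncated residue is retried in later steps
  with shares recomputed over surviving edges, so a partner whose link
  has emptied absorbs nothing further. Inside the initial step the
  α·shock export target is met by repeated rationing rounds (bounded by
  the out-degree, since every round either finishes or empties an edge).

Updates are **synchronous**: all deficit-holders cut simultaneously using
the weights at the start of the step. The ordering of countries therefore
cannot affect results, which is the reproducibility-friendly resolution of
an otherwise open scheduling choice. Deficits are always recomputed from
the state (dd = dem(0) − prod − imp + exp), never accumulated, so no
numerical drift enters the dynamics; total deficit equals the shock as an
algebraic identity at every step.

Edges pointing back toward the origin are cut like any others, which is
what produces the observed echo: part of a shock returns to and is
absorbed by the spreader (asserted on the two-block fixture).

**Termination.** The cascade stops when no country holds both a deficit
above tolerance and export capacity above tolerance. The tolerance is
relative, 1e-6 of the shock (configurable); after the one-time import
boost, total export weight is non-increasing, which guarantees
termination within the step cap (default 10,000; runs that hit it are
flagged not-converged, never silently accepted). Step indices are
bookkeeping, not calendar time.

**Homogeneity.** The model is homogeneous of degree one in calories:
scaling all weights and supplies by c scales every deficit by c while GDP
rationing is untouched. The test suite exploits this (see below) and it is
itself a tested property, exactly for power-of-two factors.

## The brute-force reference

`foodshock.oracle` re-implements the full cascade with plain Python
dictionaries and loops, recomputing exports, imports and deficits from
scratch each step, and refuses networks above 25 countries. It shares no
code with the vectorized engine; the two are compared over hundreds of
seeded (network, origin, α) cases with a 1e-9 kcal absolute bound. For
that bound to be meaningful the comparison networks are rescaled so the
largest edge weight is O(100) — at raw scale (weights up to ~1e13
kcal/year) double-precision rounding alone exceeds 1e-9 and the comparison
would only measure float noise, not algorithmic agreement.

## Synthetic network generation

The generator emulates the statistical structure of the observed 2013
calorie-trade network without fitting any real data:

* latent log-normal country "trade size" z (σ = 1.3) drives both link
  formation and edge weights, producing heavy-tailed out-strengths
  (max/median well above 50 at n = 172);
* link probability rises with exporter size and falls mildly with
  importer size, so large exporters ship almost everywhere — this yields
  the hub-dominated topology whose total-degree versus neighbor-degree
  correlation is strongly negative (disassortative), a single weakly
  connected component and undirected diameter ≤ 3;
* a scale parameter is recalibrated in a short internal loop until the
  realized density lands near the 0.358 target; reciprocity is then set
  by adding reverse links with a probability solved exactly from the
  realized one-way/reciprocated counts (target 0.610);
* GDP couples to z (and to population through a Gaussian copula), giving
  the positive GDP–export-volume association;
* weights are assigned from the importer side: every country spends an
  import budget — a uniform 10–50% fraction of its supply — across its
  suppliers with shares increasing in supplier size. Because imports
  never exceed half of supply, derived production is strictly positive
  for every country by construction, with no repair pass. (An
  exporter-side cap cannot give this guarantee, since production fails
  only when imports outrun supply plus exports.)
* populations are log-uniform on 1e5–1e9 and per-capita supply uniform on
  1800–3600 kcal/person/day, realistic country-scale ranges.

Defaults (172 countries, density 0.358, reciprocity 0.610) are the
reference study conditions. Each draw is validated for connectivity and
diameter and retried (bounded) otherwise; generation is a pure function of
the parameter set including the seed.

What the generator does **not** emulate: the real network's community and
SCC structure (the generated default is so well connected that every
ordered pair is reachable, so the "no directed path" dyadic regime is
empty there), geography, product composition, and the identity of
countries. Passing tests on synthetic networks therefore demonstrate the
correctness and qualitative behavior of the method — conservation, echo,
the escape-valve role of exports — not quantitative statements about any
real country.

## Topology conventions

Several standard measures have competing definitions; the package fixes:

* clustering: unweighted local coefficient on the undirected projection;
* betweenness: directed, unweighted, unnormalized (treating kcal weights
  as distances would invert their meaning); any log transform happens in
  the regression layer as log(1 + x) to accommodate zeros;
* hub score: principal HITS hub vector of the weighted adjacency (power
  iteration on W·Wᵀ), non-negative, unit 2-norm;
* PageRank: weight-proportional transitions, damping 0.85;
* C4: share of import calories from the four largest suppliers; an
  import-free country gets 0 (it cannot be shocked through imports); the
  ratio is clipped at 1 against one-ulp overshoot;
* ANND/ANNS: the mean neighbor degree/strength over a directional
  neighborhood. For the aggregated "tot" direction the neighborhood is
  the **union** of in- and out-neighbors (a reciprocated partner counts
  once), while the degree paired with it in the assortativity correlation
  is the standard sum k_in + k_out. Assortativity is the Pearson
  correlation over nodes with non-empty neighborhoods; a zero-variance
  case is reported as NaN.

## Experiment grid and risk measures

One cascade per (origin, α) over α ∈ {0, 0.5, 1} yields 3N² dyadic
deficits (88,752 at N = 172) in kcal/person/day of the destination
(annual deficit / population / 365; the day count is a config constant).
Derived measures:

* **exposure**: per destination, the mean deficit over all N origins,
  including its own domestic simulation (a flag excludes the diagonal for
  sensitivity);
* **hedging share**: 1 − retained/shock for each origin's own simulation,
  clipped to [0, 1], undefined for zero-production origins;
* **reserves**: per destination, the 95th percentile (linear
  interpolation between order statistics, fixed for bit-reproducibility)
  of its 3N pooled deficits, reported in kcal/person/day and as % of
  per-capita daily supply, restricted to populations ≥ 1 million;
* **vulnerability counts**: per (country, α), origins pushing the deficit
  to ≥ 250 or ≥ 500 kcal/person/day (1/8 and 1/4 of a reference daily
  intake);
* **rank score**: within each simulation destinations are ranked
  ascending by deficit with average ranks on ties (which conserves the
  total rank mass), summed over origins per (country, α) and
  log-transformed.

## Regression layer

The dyadic table carries, per (origin, destination, α) row: the deficit;
log per-capita destination GDP; the origin's shock expressed per
destination capita per day (log1p by default — the elasticity reading —
with a level switch, since the two scales are both defensible);
destination import concentration; mutually exclusive distance-regime
indicators (domestic, direct edge as the omitted baseline, finite
distance ≥ 2, no directed path); both countries' degrees, log1p
strengths, hub, log1p betweenness, PageRank × 1000 and clustering × 1000
(the ×1000 scaling matches the display convention of the reference
tables); and α dummies. Covariates are pre-shock network measures, so
they do not vary with α.

* **Tobit**: left-censored-at-zero Gaussian MLE. The likelihood is
  maximized in the Olsen reparametrization (β/σ, 1/σ), where it is
  globally concave, by damped Newton with analytic gradient and Hessian —
  quasi-Newton in the original parametrization proved fragile on the
  poorly scaled full-size design. Reported: coefficients, HC1 sandwich
  standard errors (analytic scores, numerical Hessian at the optimum),
  McFadden pseudo-R² against an intercept-only censored fit. With no
  censored rows the estimator coincides with least squares (tested to
  1e-6); an all-censored outcome is refused.
* **Negative binomial**: NB2 (variance μ + κμ²) via statsmodels with HC1
  errors; a dispersion estimate at the zero boundary triggers a Poisson
  refit with a warning.
* **OLS**: statsmodels with HC1 errors, R² and F.

Standardized display coefficients multiply each slope by its covariate's
sample SD; indicator columns pass through; zero-variance columns are
dropped with a note. Constant or collinear covariates (e.g. the
no-directed-path indicator on the fully reachable synthetic default) are
pruned before fitting; the fit functions themselves refuse singular
designs, naming the offending columns.

## Problem sizes and numerical defaults

The reference grid (172 countries × 3 α) runs in well under a minute;
property sweeps use 10–20-country networks, 100 seeded draws for
conservation and 300 cases for engine/oracle agreement; estimator
recovery uses n = 5,000 (Tobit, ~40% censoring) and n = 516 (NB2, five
seeded replicates with a 3-robust-SE criterion, reflecting the
few-percent false-alarm rate of a single replicate at that n). Cascade
tolerance 1e-6 relative to the shock; step cap 10,000; percentile method
linear; ties by average rank; PageRank damping 0.85; 365 days/year.

## Known limitations

No prices, elastic demand, stockpile drawdown or multi-origin shocks;
supplier capacity on the import channel is unlimited by assumption; the
synthetic generator does not reproduce SCC fragmentation, so
infinite-distance effects cannot be estimated on it; sign and magnitude
of regression coefficients on synthetic networks need not match those on
the real 2013 network (only the robust qualitative signs — domestic
burden positive, destination export volume protective — are asserted).
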