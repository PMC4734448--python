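# Methods

This note records the models implemented in `reefplume`, the assumptions
behind them, the defaults and why, and the limits of what the synthetic
test battery demonstrates.

## Tracer transport

The plume model is a deliberately small stand-in for a regional 3D
hydrodynamic simulation: a 2D depth-averaged advection–diffusion solver on
a regular masked grid. Vertical structure is irrelevant to the
exposure-index mathematics the package exists to exercise, so it is
omitted. The flow is prescribed (no momentum equations, tides or wind);
tracers are conservative — no sinks or sources of mass in the transport
equation — and do not feed back on the flow.

Numerics: flux-form first-order upwind advection with centred diffusion,
explicit in time. The scheme was chosen for two provable properties that
the tests rely on: exact mass conservation in closed basins (fluxes
telescope) and positivity. Its cost is numerical diffusion, acceptable at
desk scale. Positivity requires more than the two textbook constraints
(advective CFL ≤ 1 and diffusion number ≤ 0.5) enforced individually: the
solver also requires the *combined* outflow coefficient
`|u|Δt/Δx + |v|Δt/Δy + 2KΔt(1/Δx² + 1/Δy²) ≤ 1`, and refuses
configurations that violate any of the three.

River injection is not uniquely defined for a concentration tracer; we
relax the mouth-cell concentration toward 1.0 at rate `Q/V_cell` (volume
flux over cell volume, discharge read from a daily hydrograph in ML/d),
clipped to [0, 1]. Open boundaries are zero-gradient for advection
(outflow only; inflowing water carries zero tracer) and no-flux for
diffusion; mass leaving an open boundary is lost, which is intended.
Defaults: K = 50 m²/s, Δt = 600 s (3600 s in the bundled 4 km scenario),
effective depth 10 m.

The bundled scenario uses a 45 × 30 grid at 4 km resolution — the native
resolution of regional lagoon models of this kind — with an along-shore
residual current of 0.08 m/s, a two-cell land strip and one river with a
step hydrograph (300 ML/d baseflow, 80,000 ML/d through the wet season).
With these choices the full pipeline runs in a few seconds on one CPU,
and the site exposure indices reproduce the qualitative field pattern the
index was designed to capture: plume sites (< 20 km downstream) around
19–26 conc.d, marine sites (> 20 km) below 15 conc.d, decaying
monotonically with distance.

## Exposure index

Daily exceedance is `max(Conc(t) − Conc_thresh, 0)` with a *strict*
inequality at the threshold (an at-threshold day contributes nothing);
the index is the time-integral of exceedance with Δt = 1 day, in conc.d.
This form makes 20 days at 1% above threshold equivalent to 10 days at 2%
above (both 0.2 conc.d) — the property that defines the index. An
alternative that weights each day's exceedance by elapsed time `t` rather
than Δt is available (`literal_time_weight=True`) for comparison; it
breaks the equivalence above and is not the default.

Conventions: the season window (default 01 Nov – 31 Mar, 151 days across
a non-leap February) is inclusive on both ends; weekly "snapshots" are
running cumulative values, not weekly re-initialised ones; the combined
multi-river map is the per-cell sum of per-tracer indices; map values are
capped at 20 conc.d for display only (the uncapped field is kept).
Exactly 20 km downstream is classified marine: the classification rule's
two strict inequalities (< 20 km plume, > 20 km marine) leave the
boundary unassigned, and we resolve it toward the lower-exposure class.

Per-sample exposure driving the community generator is the exceedance
accumulated over the 28 days preceding the sampling date (difference of
running cumulatives). A running total from the season start would make
late-dry-season samples look maximally exposed months after the last
flood, which is not what a plankton community integrates.

## Synthetic communities

The generator emulates the *output* of an amplicon workflow — an
annotated OTU table — not reads. Expected composition per sample is
`w·riverine + (1−w)·marine(season)` over a 160-OTU universe (65 riverine,
95 marine; within-order abundances decay geometrically). The riverine
weight is `w = σ(a₀ + β·exposure + s·[wet])` with a₀ = −3 and
β ≈ 0.219 chosen so an unexposed marine site sits at w ≈ 0.05 and
20 conc.d gives w = 0.8; the wet-season offset is 0.7. The upstream
freshwater site is assigned w = 1 (pure river water). The marine
endmember swings between Pelagibacteraceae (dry) and Marine Group II
(wet) by ±35%; no quantitative seasonal effect size is available for
calibration, so this value is chosen to produce a clear but not dominant
seasonal signal. The marine endmember carries 29.6% Rickettsiales, so a
plume-site mean w near 0.31 yields the ~20% plume-site Rickettsiales
level the calibration targets.

Counts are multinomial at a uniform random depth (800–1200 reads) after
multiplying expected cell abundances by 16S copy numbers (1 for
Pelagibacteraceae/MGII up to 5 for Burkholderiales) and renormalising —
i.e., the copy-number bias is *injected*, so the correction step has real
signal to remove; a round-trip test verifies exact removal up to
multinomial error. Eukaryote reads (five OTUs, including a hydrozoan) are
appended at Poisson rate 0.05 × depth.

Environmental covariates follow a linear four-factor model: four
independent N(0,1) scores per sample; 13 variables with a single primary
loading of 0.8 (rainfall + discharge; CHLA + SS + POC + PN + PP + diuron;
DIN + Si + salinity with salinity negative; temperature + solar) and
unique noise sd 0.6, giving e.g. a rain–discharge correlation of
0.64 in expectation. Si is placed on the freshwater-mixing factor and
`bottom_depth` is site-fixed geometry outside the factor model (and
excluded from EFA) — both are this package's assignments, as no factor
membership is defined for them elsewhere. The water-quality index is a
simplified guideline-ratio score: each of SS, CHLA, PN, PP contributes +1
at/below its guideline and −1 above, averaged; default guidelines are 0.0
because the synthetic covariates live on a standardized scale.

What the generator does **not** emulate: overdispersion beyond
multinomial noise, taxon-taxon interactions, temporal autocorrelation
between consecutive sampling dates, sequencing-error OTU inflation, and
any coupling between the environmental table and the communities other
than through exposure and season. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
model, not performance on real amplicon data.

## Diversity statistics

Rarefaction ships both semantics: "expected" mode returns `depth·p_i`
per OTU (identical under with- and without-replacement subsampling),
while expected *richness* differs — `Σ 1 − (1−p_i)^depth` for the
bootstrap (with-replacement) reading and the hypergeometric
`Σ 1 − C(N−n_i, d)/C(N, d)` for classical rarefaction; both are checked
against 10,000-draw Monte-Carlo. Samples under the target depth (default
279, matching the convention of rarefying bacterial/archaeal profiles to
a common small depth) are dropped and reported, with a per-run override
available. Shannon is in nats (base-2 by flag); evenness is H/ln S with
the S = 1 case defined as 0; Chao1 uses F1²/2F2 with the bias-corrected
form when no doubletons exist. The one-sided Mann–Whitney U delegates to
scipy (exact enumeration for ≤ 12 tie-free observations, otherwise the
tie- and continuity-corrected normal approximation). EPR is computed on
unrarefied counts and is NaN when a sample has no prokaryote reads.

## Multivariate statistics

All ordination/permutation machinery is implemented here (scikit-bio
serves only as an independent cross-check in tests).

* **PERMANOVA** uses the distance-based linear model: Gower-centred
  `G = −½ J D² J`, sequential (order-dependent) sums of squares via
  nested hat-matrix projectors, pseudo-F against the residual, and raw
  row permutation (the simplest defensible null for unconditioned
  models). `p = (1 + exceedances)/(1 + n_perm)`, so p ≥ 1/(n_perm+1).
  Rank-deficient designs fail loudly, naming the aliased term.
* **IndVal** uses the group-mean-corrected form: specificity
  `A = mean_g / Σ_h mean_h`, fidelity `B` = occurrence fraction,
  statistic `max_g √(A·B)` in [0, 1] (no ×100 scaling, no group
  combinations), permutation of labels for p. Benjamini–Hochberg
  adjustment is available but off by default (raw p < 0.05 is the
  convention followed).
* **RDA** regresses the (column-centred, optionally
  condition-residualised) response on centred constraints and
  eigen-analyses the fitted values. Constraint columns fully absorbed by
  the conditioning block are dropped (zero constrained variance results
  when all are); genuinely collinear constraints raise with the dependent
  columns named. The permutation test permutes rows of the residualised
  response. Stepwise selection uses an RSS-based AIC analogue,
  `n·ln(RSS/n) + 2(k+1)` — no canonical AIC exists for distance-based
  RDA, so this fixed definition is documented rather than inferred; ties
  break toward the first-listed term and aliased candidates are never
  added.
* **EFA** is iterated principal-axis factoring on the correlation matrix
  (SMC-initialised communalities, capped at 0.995; convergence 1e-6, hard
  iteration cap with a loud failure), varimax rotation, factors ordered
  by explained variance and sign-anchored at their largest loading.
  Parallel analysis compares observed eigenvalues against the 95th
  percentile of column-permuted data (100 permutations), counting
  consecutive exceedances. Factor scores use the regression (Thurstone)
  method. Recovered factor *labels* are arbitrary; tests compare
  memberships and Tucker congruence, not label order.

## Pipeline

`run_pipeline` executes classify → simulate → exposure → synthesis →
diversity → multivariate in order, single-process. Per-stage seeds are
spawned from the master seed via `SeedSequence` and recorded in the
manifest together with a config hash, output paths and stage status;
identical config + seed reproduces byte-identical TSV outputs. Supplying
an external OTU table (BIOM-JSON or TSV) plus metadata skips simulation
and synthesis. BIOM 1.0 JSON is read and written directly (sparse
encoding, observation metadata carrying taxonomy, copy number and
domain); gridded fields go to NetCDF through xarray's scipy backend.

## Known limitations

* The 2D solver's first-order upwinding over-diffuses plumes; absolute
  exposure values depend on grid resolution and K and should be read
  comparatively, not absolutely.
* The logistic exposure→mixing link is monotone by construction; the
  package cannot represent hysteresis or lagged community responses.
* PERMANOVA's sequential SS makes multi-term R² order-dependent; the
  pipeline reports the configured order (category before season).
* Parallel analysis is conservative at small n; the bundled 42-sample
  scenario typically retains 3 of the 4 planted factors, while the
  n = 200 design recovers all 4.
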