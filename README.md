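# reefplume

River-plume exposure modelling and 16S community statistics for coastal
lagoon microbial monitoring.

Inshore coral-reef lagoons receive episodic pulses of river floodwater
carrying sediments, nutrients and herbicides. `reefplume` is a desk-scale,
fully tested implementation of the computational chain used to relate that
river influence to planktonic microbial community structure:

1. **Passive-tracer plume simulation** — conservative tracers released at
   unit concentration from river mouths are advected by a prescribed
   coastal flow and spread by horizontal diffusion on a 2D depth-averaged
   grid (flux-form first-order upwind + explicit centred diffusion; no
   sinks or sources besides river injection and open-boundary outflow).
2. **Cumulative river-exposure index** — for every grid cell,

   `Conc.Days = Σ_t max(Conc(t) − Conc_thresh, 0) · Δt`  (Δt = 1 day),

   with `Conc_thresh` = 1% of the source concentration, accumulated over
   the wet season (01 Nov – 31 Mar) and expressed in concentration × days
   (conc.d). Twenty days at 1% above the threshold and ten days at 2%
   above it both give 0.2 conc.d. Maps are capped (default 20 conc.d) and
   weekly running snapshots are kept.
3. **Site classification** — upstream of the mouth → riverine; downstream
   < 20 km → plume; ≥ 20 km → marine.
4. **Synthetic community generator** — OTU tables built by mixing a
   riverine endmember (Burkholderiales, Sphingobacteriales,
   Xanthomonadales; ~65 OTUs) with a seasonally modulated marine endmember
   (Pelagibacteraceae, *Prochlorococcus*, Marine Group II, OCS155;
   ~95 OTUs) through a logistic link on exposure, with 16S copy-number
   bias injected and eukaryote contamination appended; plus a 14-variable
   environmental table with a planted four-factor correlation structure.
5. **Diversity statistics** — rarefaction (expected/bootstrap and
   draw/hypergeometric), copy-number correction
   `(a_i/c_i)/Σ_j(a_j/c_j)`, richness, Shannon–Wiener index and evenness,
   Chao1, one-sided Mann–Whitney U, eukaryote/prokaryote read ratio.
6. **Multivariate statistics** (from scratch) — Hellinger transform and
   distance, PCoA, PERMANOVA with sequential SS and permutation p,
   indicator-species analysis (IndVal = √(A·B)), partial RDA with an
   AIC-based stepwise selection, Pearson screening, and exploratory
   factor analysis (principal-axis factoring, varimax, parallel
   analysis).

## Worked example

Run the bundled scenario (one river on a 45 × 30 grid at 4 km resolution,
seven monitoring sites, six sampling dates spanning wet and dry seasons):

```bash
reefplume run-all --outdir run --seed 1
reefplume report --rundir run
```

which prints (abbreviated):

```json
{
  "permanova": {
    "category": {"R2": 0.439, "p": 0.001},
    "season":   {"R2": 0.071, "p": 0.001}
  },
  "n_indicator_otus": 104,
  "efa_factors": 3,
  "mixing_fraction_truth_correlation": 0.9997
}
```

Reading: site category (riverine/plume/marine) explains ~44% of the
Hellinger-distance variation in the synthetic communities and season ~7%,
both significant at 999 permutations — the spatial gradient dominates the
seasonal one. 104 OTUs are significant indicators of a site category, and
the riverine mixing fraction re-estimated from the OTU table (copy-number-
corrected abundance summed over riverine-endmember taxa) correlates with
the generator's truth at r ≈ 1. Per-site exposure indices decay
monotonically downstream (25.9 conc.d at 4 km through 19.4 at 16 km to
10.5 conc.d at 60 km in this scenario).

Individual stages are available as subcommands
(`simulate-tracers`, `exposure-map`, `classify-sites`, `synth-data`,
`analyze diversity|ordination|permanova|indval|rda|efa`) and as plain
library calls (see `reefplume/pipeline.py` for the orchestration).

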