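# Methods

This note documents the models and procedures implemented in `picoseason`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducibility.

## Water-column features

**Mixed layer depth (MLD).** The density-offset criterion: the shallowest
depth where σₜ(z) ≥ σₜ(z₀) + Δσ, with Δσ = 0.125 kg m⁻³ and the
shallowest sample standing in for the surface. The crossing is linearly
interpolated in σₜ between the bracketing samples; the offset rule alone
does not prescribe sub-sample behaviour, and linear interpolation is the
least-structured choice. A cast whose deepest sample never reaches the
threshold is *bottom-limited*: it returns the deepest sampled depth plus a
flag rather than "undefined", so deep-mixing detection still works on
300 m casts whose mixed layer extends to or beyond the profile bottom.
MLD is monotone in Δσ (a property test enforces this).

**Light depths.** Euphotic zone depth is where PAR falls to 0.1% of its
value at the shallowest sample; a 1% level serves as the deep comparison
point during deep mixing, when no DCM exists. Interpolation is linear in
log(PAR) versus depth — exact for exponential attenuation
PAR(z) = PAR₀·e^(−kz), where the depths are ln(1/f)/k. Zero PAR readings
are excluded from the log interpolation; if the crossing falls between the
last positive reading and a zero reading, the first zero sample's depth is
used. A level never reached within the cast is absent, not extrapolated.

**DCM region.** The deep chlorophyll maximum is read as the contiguous
depth interval, containing the fluorescence maximum, where fluorescence
stays at or above 65% of the maximum (i.e. within 35% of it), with the
boundary depths linearly interpolated. The alternative reading — a fixed
±35% *depth* span — is rejected as unit-dependent. Ties for the maximum
resolve to the shallowest depth. The region counts as a true DCM only when
the mixed layer lies above its upper bound; a surface-trapped maximum
under a deep mixed layer is not a DCM. As the fraction parameter tends to
0 the region collapses to the maximum's depth.

## Stability-period state machine

Four annual phases are tracked over time-ordered casts:

| label | phase | trigger |
|---|---|---|
| DM | deep mixing | MLD > euphotic depth (highest precedence, from any state) |
| ST | spring transition | from DM, MLD ≤ 100 m and the DM trigger released |
| SS | stratified summer | from ST, a true DCM exists and MLD < its upper bound |
| AT | autumn transition | from SS, MLD ≥ the DCM's upper bound (first entrainment) without deep mixing |

Labels persist between observations. Transitions *cascade* within a single
observation: if a sparsely sampled series jumps from deep winter mixing
straight to a 40 m summer mixed layer, the machine passes DM→ST→SS in one
step rather than lagging a state behind the water column. DM precedence
means a mid-winter restratification followed by renewed deep mixing
re-enters DM. The first observation is seeded by whichever trigger holds
(DM > SS > ST). Casts lacking PAR or fluorescence simply cannot fire the
rules that need them; a series in which no cast ever satisfies any trigger
is an error, not a silent guess. The ~100 m spring threshold is an exact
parameter (`st_mld_threshold_m`), and an optional running-median MLD
smoother (off by default) is available for noisy cast series.

**Vertical zones.** Each bottle sample gets exactly one zone, first match
wins: `surface` (≤5 m); `dcm` (stratified-period cast, depth inside the
DCM region); `light1pct` (deep-mixing cast, within ±10 m of the 1% light
level — a tolerance is needed because bottles sample discrete depths);
`ml` (≤ MLD); `below_euphotic`; else `other`. Rules whose feature is
absent are skipped.

## Community analysis

**Saturation filter.** The endpoint slope of the analytical rarefaction
curve E[S(n)] = Σᵢ[1 − C(N−Nᵢ, n)/C(N, n)] reduces at n = N to f₁/N, the
singleton fraction — only a read that is its ASV's sole representative can
remove richness when one read is dropped. Samples with slope ≥ 0.1 are
rejected as unsaturated. Samples with < 50 plastid reads are *flagged*,
not dropped: plastid-denominator analyses exclude them while whole-library
views keep them (deep casts legitimately carry few plastid reads).

**Normalization.** Relative abundances are computed per sample over one of
three denominators: all reads, plastid reads, or prasinophyte reads (the
prasinodermophytes, "Class VI", count as prasinophytes). A sample with a
zero denominator is absent from that view — never a row of zeros. In
period × zone summaries, a sample that has the denominator but lacks a
unit contributes 0 for that unit; means are arithmetic, sd is the sample
standard deviation (absent at n = 1).

**Quadrant analysis.** Over samples at ≤140 m with both Chl *a* and the
prasinophyte-of-plastid fraction present, both variables are thresholded
at their 75th percentiles (linear interpolation between order statistics —
the convention matters because the thresholds are reported quantities).
Values exactly at a threshold fall in the "≤" half, so the
high-chlorophyll/high-prasinophyte quadrant requires strict exceedance on
both axes. The quadrants partition the eligible set.

**Persistence.** Detection is any positive count (an optional
relative-abundance floor exists, default 0 — no floor is assumed).
Restricted to ≤140 m and the analysis years (default 2017–2019; the first,
incompletely sampled year is excluded), each ASV's set of stability
periods and years with ≥1 detection is collected. ASVs with exactly one
read in the restricted data (singletons) are excluded before
categorization; "singleton" is read as one *read*, not one sample of
occurrence. Categories: ephemeral (1 period), intermediate (2–3),
persistent (4) — the intermediate class makes the spectrum explicit even
though only the endpoints are conventionally named. Per-period ASV sets
and per-year overlaps of SS-only ASVs are emitted for Venn/UpSet-style
counting.

**Detection limits.** Nutrient values below the instrument floor
(nitrate+nitrite 0.05, phosphate 0.03 µmol kg⁻¹) are reported as zero;
boundary values pass through.

## Cross-marker linking

For a 16S ASV that cannot be placed to species (uncultured species defined
only by 18S), the within-genus relative abundance of the 16S ASV and of
the candidate species' 18S ASVs should co-vary across samples if they are
the same organism. The comparison set is samples where either side is
detected *and* the genus has ≥10 reads in **both** markers (the per-marker
reading of the subset rule; applying it to only one marker would let
near-zero denominators in the other inject noise). A sample passing the
genus filter but lacking the unit enters with fraction 0. Link = Spearman
ρ > 0 with two-sided p < 0.05; a significant *negative* correlation is
reported but never flagged linked, since negative co-occurrence cannot
indicate identity. Under this definition the expected false-link rate on
truly independent pairs is at most α (about α/2, since only the positive
tail can link). Fewer than 3 qualifying samples, or constant fractions,
leave the link indeterminate.

## Statistics

Midranks everywhere. Spearman ρ is the Pearson correlation of midranks;
two-sided p from the t approximation for n ≥ 10 and from exact
enumeration of all n! rank permutations for n < 10. Kruskal–Wallis uses
the tie-corrected H (division by 1 − ΣT/(N³−N)); all-tied data returns
H = 0, p = 1 by convention. Dunn's z uses the pooled-rank variance
N(N+1)/12 − ΣT/(12(N−1)) with Holm adjustment by default (none and
Bonferroni available). ANOSIM midranks all n(n−1)/2 pairwise distances and
uses R = (r̄_B − r̄_W)/(M/2); p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm)
over seeded label permutations, 9999 by default. The distance for ANOSIM
on Hellinger-transformed abundances is Euclidean (equivalently the
Hellinger distance); Bray–Curtis is available by flag. Normality
pre-testing is deliberately omitted: the nonparametric tests are applied
unconditionally.

The chi-square reference for H is asymptotic; its calibration check in the
test suite uses three groups of 30, where the approximation error is
negligible against a Kolmogorov–Smirnov uniformity test at α = 0.01.

## Synthetic-data generator

**Physics.** A monotone-cubic (PCHIP) curve through twelve planted
monthly MLD anchors (default winter ≈ 250–280 m, summer ≈ 20 m) forces the
annual cycle. Daily ground-truth labels come from running the *same*
state machine on noise-free daily profiles built from that curve — truth
and analysis share one rule set by construction, and the daily truth is
cached across seeds because noise never enters it. Emitted casts (default
one per month, on a 1–300 m grid at 2 m, with 8 bottle depths) jitter the
MLD (sd 4 m) and add sensor noise (σₜ sd 0.002 kg m⁻³, 5% fluorescence,
2% PAR). σₜ is generated directly — uniform above the planted MLD, a
linear pycnocline below, arranged so the +0.125 crossing lands exactly at
the planted depth (no equation of state is needed on the analysis path).
PAR decays exponentially (k = 0.046 m⁻¹, euphotic depth ≈ 151 m);
fluorescence is a Gaussian DCM (center 100 ± 3 m jitter, width 20 m) when
stratified and an elevated mixed-layer signal during deep mixing.

**Community.** Per sample: a group-level composition drawn from a
Dirichlet around the (period, zone) template, a library size from a
lognormal matched to mean 60,279 / sd 26,939 reads, and multinomial
counts. Templates plant the prasinophyte fraction of plastid reads per
(period, zone) — 0.463 in the deep-mixing mixed layer, 0.336 at its
surface, 0.29 at the DCM, 0.036 at the stratified-summer surface, etc. —
with the non-prasinophyte plastid mass split prymnesiophyte :
stramenopile : other = 0.346 : 0.595 : 0.059. The group-level Dirichlet
concentration (28) was set so the between-sample spread of the DM
mixed-layer prasinophyte fraction is ≈ ±0.24, the scale real amplicon data
of this kind shows; the within-group ASV concentration is 50. Values the
source system does not pin down were chosen once as plausible for an
oligotrophic gyre and documented here: plastid reads are 12% of the
library in the euphotic zone (4% below it), cyanobacteria 33%,
heterotrophs the rest; the stratified-summer surface flips the
prasinophyte class split from Class II dominance toward Classes I/IX.
Persistent ASVs carry template mass in every period; summer ephemerals
only during SS. A *Micromonas* species latent (Dirichlet, concentration 2)
is shared with the 18S marker, scaled by per-species copy-number
multipliers (0.6–5×) with 20% lognormal noise — only rank agreement
matters to the linking stage, so the multiplier spread is a free
parameter. One planted species' 18S abundance follows an independent
latent (the null pair). Bottle Chl *a* is proportional to the noise-free
fluorescence at the sampled depth (0.2 µg kg⁻¹ per RFU, 15% noise);
nutrients increase below ~90 m from near-zero surface values so that some
readings fall below the detection limits. A focused helper
(`simulate_linked_pair`) builds minimal genus-only paired tables for link
calibration experiments.

**What the generator does not emulate.** No advection, eddies, fronts or
interannual trends; no sequence-level artifacts (chimeras, index hopping);
no taxonomic misassignment; no copy-number variation within a species; no
nutrient–biology coupling (nutrients exist to exercise detection-limit
handling and summaries). Passing tests therefore demonstrate that the
*algorithms* recover planted structure under realistic sampling noise and
compositional dispersion — not that the pipeline is robust to artifacts
the generator does not model.

## Problem sizes and determinism

Default experiment sizes: period recovery over 10 seeds of the 12-cast
year (99%+ observed; 100% required and observed at zero noise); with
monthly sampling, a single spring cast can jitter across the ~100 m
threshold, so the sampled label sequence occasionally skips the short
spring transition even though the planted daily sequence always contains
the full DM→ST→SS→AT cycle. Persistence recovery over 100 independent
synthetic years; cross-marker calibration over 200 linked and 1000 null
replicates at 30 shared samples; statistics oracles over 200 random
datasets plus 2000-replicate uniformity checks. All randomness flows
through `numpy.random.default_rng` seeds; fixed seeds give byte-identical
outputs, different seeds different data.

## Known limitations

- The state machine assumes the annual succession; multi-year gaps or
  polar regimes (no stratification) would leave it in a stale state.
- Bottom-limited MLDs understate the true mixed layer; downstream zoning
  treats the whole cast as mixed layer in that case.
- The exact-permutation Spearman path enumerates n! permutations and is
  only used below n = 10.
- ANOSIM p-values are permutation-based and inherit the 1/(n_perm+1)
  resolution floor.
- The quadrant thresholds are data-dependent percentiles: they shift with
  the eligible-sample window, so cross-dataset comparisons must recompute
  them, not reuse values.
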