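# picoseason

Seasonally and vertically resolved analysis of picophytoplankton amplicon
communities in subtropical ocean time series.

Subtropical gyres alternate annually between winter deep convective mixing
and summer thermal stratification. That physical cycle structures the
eukaryotic picophytoplankton — prasinophyte green algae in particular —
both in time (a succession of water-column stability periods) and in the
vertical (surface, mixed layer, deep chlorophyll maximum). `picoseason`
implements the full analysis chain for paired CTD + amplicon time series
of this kind, for biological oceanographers and microbial ecologists:

1. **Hydrography** (`picoseason.hydro`) — per-cast physical features and a
   stability-period state machine:
   - mixed layer depth: shallowest depth where σₜ(z) ≥ σₜ(surface) + 0.125
     kg m⁻³, linearly interpolated;
   - euphotic zone depth (0.1% of surface PAR) and a 1% comparison level,
     log-linear in PAR;
   - DCM region: the contiguous interval where fluorescence stays within
     35% of its maximum (F ≥ 0.65·Fmax), a true DCM only when the mixed
     layer lies above it;
   - stability periods: **DM** (deep mixing, MLD > euphotic depth),
     **ST** (spring transition, MLD shoaled to ~100 m), **SS** (stratified
     summer, MLD above the DCM), **AT** (autumn transition, first
     entrainment of the DCM into the deepening mixed layer).
2. **Community** (`picoseason.community`) — rarefaction-saturation
   filtering (endpoint slope f₁/N < 0.1), relative abundances over total /
   plastid / prasinophyte denominators, period × zone mean ± sd summaries,
   the Chl *a* × prasinophyte-fraction quadrant analysis at 75th-percentile
   thresholds, and categorization of ASVs from **ephemeral** (one
   stability period) to **persistent** (all four), singletons excluded.
3. **Cross-marker linking** (`picoseason.crossmarker`) — ties unplaced 16S
   plastid ASVs to 18S-defined candidate species by Spearman correlation
   of within-genus relative abundances across shared samples (≥10 genus
   reads in each marker).
4. **Statistics** (`picoseason.stats`) — formula-level Spearman,
   Kruskal–Wallis with tie correction, Dunn post-hoc z-tests, the
   Hellinger transform, and ANOSIM
   (R = (r̄_B − r̄_W)/(M/2) over midranked pairwise distances) with seeded
   permutation p-values.
5. **Synthetic data** (`picoseason.synth`) — a generator that emulates a
   Bermuda-like annual cycle (winter MLD ≈ 250–300 m, DCM at ~80–120 m,
   library sizes ≈ 60,279 ± 26,939 reads, DM mixed-layer prasinophyte
   fraction near 46% of plastid amplicons) and plants ground truth for
   every stage: daily period labels, per-profile MLD/DCM, persistent and
   summer-ephemeral ASVs, and 16S↔18S pairs sharing a latent abundance.

## Worked example

Generate a synthetic year, classify it, and summarize the community:

```bash
picoseason simulate --seed 5 --outdir sim
picoseason hydro --ctd sim/ctd.csv --out-features features.csv --out-timeline timeline.csv
picoseason community --asv sim/asv16.tsv --tax sim/taxonomy.tsv \
    --meta sim/meta.tsv --features features.csv --timeline timeline.csv \
    --bottle sim/bottle.csv --outdir comm
```

The timeline lists one stability label per cast with the rule that fired
(transition rows shown; held states carry a `hold (...)` trigger):

```
profile_id,timestamp,label,trigger
P20170101,2017-01-01T00:00:00,DM,seed: MLD > euphotic depth
P20170401,2017-04-01T00:00:00,ST,MLD shoaled to ST threshold
P20170501,2017-05-01T00:00:00,SS,MLD above DCM upper bound
P20171001,2017-10-01T00:00:00,AT,MLD entrained DCM upper bound
P20171201,2017-12-01T00:00:00,DM,MLD > euphotic depth
```

`comm/summary_period_zone.csv` then holds the period × zone group means,
e.g. the deep-mixing mixed-layer prasinophyte classes (fractions of
plastid amplicons; the four class rows sum to ≈0.48, a one-year draw
around the planted 0.463):

```
period,zone,unit,mean,sd,n
DM,ml,prasinophyte-CI,0.0844,0.1218,19
DM,ml,prasinophyte-CII,0.2507,0.2025,19
DM,ml,prasinophyte-CIX,0.1018,0.1394,19
DM,ml,prasinophyte-CVI,0.0470,0.0675,19
```

and `comm/persistence.csv` recovers the planted ecology — e.g.
`asv16_ostreoOII,4,"AT,DM,SS,ST",1,persistent` (detected in all four
periods) and `asv16_eph1,1,SS,1,ephemeral` (stratified summer only).
Linking a planted *Micromonas* candidate species across markers:

```bash
picoseason crossmarker --asv16 sim/asv16.tsv --asv18 sim/asv18.tsv \
    --tax sim/taxonomy.tsv --pairs pairs.tsv --out links.csv
```

reports the shared-sample count, Spearman ρ and the linked flag
(two-sided p < 0.05 and ρ > 0) per pair:

```
asv16_id,species18_label,n_samples,rho,p_value,linked
asv16_81,m_cand1,57,0.9067,2.79e-22,True
```

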