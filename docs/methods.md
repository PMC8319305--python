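# Methods

`cagedrive` models the suppression of age-structured *Anopheles gambiae*
populations in large indoor cages by a CRISPR homing gene drive inserted in
the female-specific exon of *doublesex*, and infers cage life-history
parameters from the resulting time series by rejection ABC. This note
documents the model, its parameters and defaults, the numerical choices, and
what the synthetic-data experiments do and do not demonstrate.

## Genetic model

Three alleles exist at the target locus: wild type `W`, the drive cassette
`D` (with a dominant RFP marker, so "carrier" is observable in larvae), and a
non-functional resistance allele `R2` (frameshift/disrupting repair product).
No functional-resistant `R1` state is modelled: the target sequence is under
strong functional constraint and no restorative allele was observed against
this drive; the allele enum is the extension point if one is ever needed.

Gametogenesis in a `W/D` germline converts the `W` allele to `D` with
probability `h` (homing). Of the `1 − h` non-homed gametes, a fraction `rho`
become `R2` and the remainder stay `W`. All other genotypes segregate
Mendelian. Homing acts in both sexes at the same `h` by default (the
germline promoter driving Cas9 is active in both); sex-specific rates are
available (`h_male` / `h_female`).

Phenotype: females with no intact `W` copy (`D/D`, `D/R2`, `R2/R2`) develop
as sterile intersex and never mate or lay. Males are always fertile.
Fertile females carry a fertility multiplier determined by their parents'
carrier status — `f_pat` if the father carried the drive, `f_mat` if the
mother did — modelling nuclease deposition / somatic leakage. Two open
design points are exposed as configuration:

- **Both parents carriers**: default `min(f_pat, f_mat)` (no double
  penalty); `product` available.
- **Scope**: default `all_daughters` — the multiplier applies to every
  fertile daughter of a carrier parent, the parental-deposition reading;
  `carrier_daughters` restricts it to daughters that themselves inherited
  the drive (pure somatic-leakage reading).

## Cage simulator

One cage is advanced in daily steps; within each day the order is fixed:
deaths and ageing → juvenile development (hatch, pupal re-stocking,
eclosion) → mating → scheduled introductions → egg laying/collection.
Introductions are pupae, so they cannot mate or lay the day they arrive;
newly eclosed adults become eligible the following day.

State is aggregated: adults are counted by (age, genotype pair, parental
flags, mating status, stored mate genotype). Within such a class every
individual has identical event probabilities, so binomial/multinomial draws
on class counts follow exactly the same stochastic law as per-individual
simulation — this is an exact aggregation, not an approximation — and it is
what makes hundreds of year-long replicates affordable on one CPU.

**Protocol.** Collections run on a twice-weekly grid (days 0 and 3 of each
week). Establishment: 800 sexed wild-type pupae at day 0, then 400 per
collection through day 21. Thereafter the cage re-stocks itself with up to
400 randomly selected pupae from its own egg output per collection (wild-type
top-up during the 74-day pre-release phase only, mirroring the study's
supplementation). Releases add heterozygous drive males on the first two
re-stocking occasions after day 74: 71+72 (low, ≈12.5% allele frequency
relative to the estimated standing population) or 142+143 (medium, ≈25%).
Egg counts are exhaustive; larval RFP screening is capped at 1000 per
collection (hypergeometric subsampling). Default monitoring ends at day 384
(~310 days after release); forecasting runs extend the horizon.

**Adult survival.** Default is an age-senescent Gompertz daily hazard whose
median lifespan ramps linearly from 6 days (experiment start) to 11 days
(end), shape 0.45. Senescence is forced by the study's own calibration: a
6-day *median* lifespan together with a ~574-adult standing population under
800 introduced pupae/week implies a *mean* lifespan of ~5 days — below the
median, which no constant-hazard (geometric) model can produce (geometric
would give mean 8.2 d and ~930 adults). The shape value makes the
establishment regime sustain ≈600 adults, the closest the integer-day
median-6 constraint allows to the reported ~574. A `geometric` survival mode
(constant daily survival `0.5^(1/median)`, linearly interpolated over the
experiment) is retained as configuration, and `calibrate_daily_survival`
implements that simple bridge from an observed median. An optional female
survival advantage (≥1 multiplier) reflects the observation that females
outlive males in large cages; default off (1.0).

**Life history defaults** (the inferred posterior means where the study
prints them): eggs per batch `lambda_eggs = 116` (Poisson; negative-binomial
overdispersion available via `batch_dispersion`, since Poisson batches
under-represent the egg-output variability of real cages); laying
probability per twice-weekly opportunity `p_lay = 0.14` times the female's
fertility multiplier; `rho = 0.5`; `f_pat = 0.35`; `f_mat = 0.5` (its
posterior resembled the flat prior, so the prior mean is the natural
default). Homing `h = 0.975` (transmission (1+h)/2 ≈ 0.99, in line with
measured transmission for this drive; at `h = 0.95` the model accumulates an
R2 fraction among non-drive alleles an order of magnitude above the <1%
observed). Juvenile schedule: hatch day 2, pupation day 11, eclosion day 13
post-oviposition (standard 28 °C rearing); egg-to-pupa survival 0.8. Mating:
unmated fertile females ≥1 day old mate with probability 0.6/day, mate drawn
from current male genotype frequencies, lifelong sperm storage. There is no
larval density dependence beyond the 400-pupae re-stocking cap — larvae were
reared at fixed density in the study, and the cap is the regulating
mechanism; this is a known simplification of aquatic-stage ecology.

**Suppression** is called from the egg record: the first collection from
which every later collection recovered zero eggs; a later rebound cancels
earlier zeros, and a series still producing eggs at its final collection has
no suppression day (censored).

## ABC inference

Five parameters are inferred: `f_pat`, `f_mat`, `lambda_eggs`, `p_lay`,
`rho`. Priors are independent uniforms — `f_pat, f_mat, rho ∈ (0,1)`,
`lambda_eggs ∈ (20, 300)`, `p_lay ∈ (0.01, 0.5)` — wide enough to contain
every published credible interval with margin.

Summary statistics per cage (concatenated over an arm's replicate cages,
sorted by replicate id): carrier frequency at 8 evenly spaced fractions of
the monitoring period (last observation carried forward across unscreened
collections; leading gaps are zero), mean and variance of `log(eggs+1)`, and
the suppression day censored at the final collection. These capture the
three features the study tracks: invasion speed, egg-output level and
variability, and suppression timing. The distance is Euclidean after
per-component scaling by the robust SD (1.4826×MAD) of the simulated
reference table; zero-scale components are compared absolutely. Both the
statistic suite and the distance are pluggable — the published analysis's
exact suite lives in its supplementary material and linked repository, so
this module fixes a reasonable substitute rather than a reconstruction.

Rejection is the plain retain-k-best scheme (defaults: keep 200 of 50,000,
the study's budget; reduced scales for desk experiments), one forward
simulation per draw replicating the observed arm structure, ties broken by
draw index, failed simulations excluded with a logged warning. Posterior
summaries are means, equal-tailed 95% intervals and the sample covariance.
Posterior-predictive forecasting resamples retained draws uniformly,
simulates the arm, and reports suppression-day quantiles from release,
censored at the horizon.

`printed_posterior()` encodes the published posterior summaries: the means,
plus per-parameter distributions (Beta/Gamma) moment-matched to the printed
means and 95% intervals. The published posterior has negative covariance
between `f_pat` and `f_mat` (magnitude unprinted), so these marginals must
not be multiplied into a joint distribution: independent sampling
over-weights the joint-low corner, where heterozygous females of both
descent types are near-sterile and the drive can stall — dynamics the
published predictive runs never showed. Forecast experiments therefore run
at the printed posterior-mean values, with run-to-run variation from
demographic stochasticity.

## Analytics

Carrier frequency is RFP-positive over screened larvae; drive-allele
frequency uses true genotype counts when available, otherwise inverts the
carrier fraction under random mating (`q = 1 − sqrt(1 − c)`, flagged as
estimated). Fluctuation autocovariance first-differences the series (to
remove the sigmoidal invasion trend) and uses the standard biased sample
autocovariance at lags in collections (two weeks = lag 4 at two collections
a week); the exact published detrending is supplementary, so the options are
exposed. R2 bookkeeping reports R2/(W+R2) with a 0.25% detection threshold
(the amplicon-sequencing error floor); the fraction is undefined at drive
fixation. Survival analysis is a Kaplan–Meier product-limit fit (via
`lifelines`) with the median read as the smallest time with S(t) ≤ 0.5.

## Synthetic data

`generate_study` emulates the study's design — duplicate control, low- and
medium-release cages, twice-weekly collections, releases at day 77/80 —
with ground truth defaulting to the printed posterior means, and serialises
the truth next to the data. The observation process subsamples larval
screening only; egg totals are exact (the study counted all eggs by
software). The default horizon is day 460, mirroring the study's practice of
monitoring until full suppression (under the default truth nearly all
release cages suppress inside it).

What the generator does **not** emulate: the two-weekly oscillation the real
cages showed in drive frequency (the model's mixing is smoother — the study
itself notes the fluctuations were absent from simulated series; our
screening process does produce a release-pulse transient, but not sustained
cohort cycling), overdispersed egg output beyond the Poisson default,
position/cage effects (real cages differed up to two-fold in mean egg
output), and any larval competition. Passing parameter-recovery tests on
these bundles therefore demonstrates that the inference machinery is
self-consistent at the study's scale and noise structure — not that it would
be unbiased against real cages whose data-generating process differs in the
ways above.

## Numerical and scale choices

Forward runs are deterministic given (configs, seed); per-cage and per-draw
streams are spawned from a root `SeedSequence` so experiments parallelise
and reproduce. Extinct cages stop stepping and pad zero records. Desk-scale
inference experiments use a quarter-scale protocol (100-pupae cap, 28-day
initiation, ~150-day post-release window, releases 18+17 / 35+35 — the same
~12.5%/25% strength relative to the smaller standing population), which cuts
a forward simulation to ~35 ms; forecast experiments use the full protocol
with 200 runs per arm and a 900-day post-release censoring horizon. The ABC
recovery experiment shares one 5000-draw reference table across repeated
pseudo-observed datasets, which is legitimate for rejection ABC because the
table is independent of each observation.

## Known limitations

- The upper tail of suppression times is heavier than the published model's:
  in roughly 1% of low-release runs the population bottleneck ends with all
  drive alleles lost by drift and fertile W/R2 remnants re-founding the cage
  (a rebound), and a few further runs clear the wild-type reservoir only
  after day 560. The published model reported no such outcomes in 1000 runs;
  its supplementary mating and juvenile details (e.g. any mate-finding
  failure at low density) are not reproducible from the main text, and no
  such mechanism was added here.
- `f_mat` is nearly unidentifiable from cage data (as in the study); its
  default is a convention, not an estimate.
- The model underestimates real egg-output variability unless
  `batch_dispersion` is set; control-cage variance summaries are
  correspondingly optimistic.
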