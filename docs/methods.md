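# Methods

This note documents the models behind `crossplan`, the conventions and
defaults, the numerical choices, and what the synthetic test conditions
do and do not demonstrate.

## Time and units

One *breeding season* is the unit of time everywhere: each active dam
farrows one litter per season, productive lifetimes are counted in
seasons of service, and economics are itemized per season. Trait values
are in trait units (the examples use days to 100 kg, AGE, where lower
is better); genetic parameters are the narrow-sense heritability h² and
the additive variance σ²ₐ, with residual variance σ²ₑ = σ²ₐ(1 − h²)/h².

## Nucleus simulation

The nucleus is simulated animal by animal under the infinitesimal
model. True breeding values are deviations from the breed's initial
mean; an offspring receives

    tbv = ½(tbv_sire + tbv_dam) + m,   Var(m) = ½ σ²ₐ (1 − (F_s + F_d)/2),

so selection response, the Bulmer-effect variance decline and
drift/inbreeding dynamics all emerge without simulating loci. This
reproduces the expectations of a locus-based simulation for the
quantities reported here (gain, variance, inbreeding) at a fraction of
the cost; what it cannot show is anything allele-specific (fixation,
major genes, genomic selection accuracy as an outcome).

Season order of events:

1. **Promotion** — candidates born the previous season fill vacant
   breeding slots, best EBV first within sex (stable tie-break by id);
   the unselected are sold.
2. **Mating** — sires are allocated to dams near-equally at random; each
   dam produces `litter_size` offspring with random sex.
3. **Preselection** — `nfam` offspring per litter are kept as candidates
   uniformly at random and phenotyped (y = tbv + e); the rest are sold
   at birth.
4. **Evaluation** — pedigree BLUP over the whole recorded pedigree, or
   the accuracy-parameterized pseudo-EBV (below).
5. **Culling** — stock whose service time has reached its productive
   lifetime leaves, oldest first, but never more than this season's
   candidate cohort can replace: when a sex runs short of candidates the
   oldest stock is held over so the herd never shrinks (herd
   maintenance, as practiced). If an entire sex's stock is due out and
   no candidate of that sex exists, the simulation stops with an error
   naming the season.

Founder service starts are staggered across the productive lifetime so
the herd is age-structured from season 1 and replacement runs at ~1/y
per season — the steady overlapping-generation state the gene-flow
machinery assumes — rather than the whole herd turning over at once.

**Pedigree BLUP.** Single-trait animal model with an overall mean as
the only fixed effect, λ = (1 − h²)/h², A⁻¹ assembled sparsely by
Henderson's rules with Mendelian-sampling variances adjusted for
parental inbreeding (Meuwissen–Luo coefficients), solved with a sparse
direct factorization. Agreement with a dense direct solve is tested to
1e-8. At h² ≈ 1 the MME degenerate and the phenotype-deviation shortcut
is used (records minus mean, parent average for unrecorded animals).

**Accuracy mode.** EBV = r²·tbv + e with Var(e) = r²(1 − r²)σ²ₐ, so
corr(EBV, TBV) → r. This is a stand-in for marker-based evaluation when
only the *accuracy* of the evaluation matters to the design question; it
deliberately has no data model.

**Reported aggregates.** The per-season gain Δg is the newborn-cohort
mean TBV minus the previous cohort's (season 1 is measured against the
founder cohort). *Relative genetic progress* is the favorable-signed
total gain divided by the initial genetic standard deviation and by the
number of seasons — the normalization is a package convention, stated
here because no standard exists. Inbreeding increment and variance
decline are final-minus-initial cohort statistics, averaged over
replicates. Replicate r of breed b uses a seed derived from
(master seed, breed label, r) so replicates and breeds are independent
but fully reproducible.

## Gene-flow prediction

State classes per tier: one newborn *cohort* class for every tier that
breeds (nuclei, crossbred dam line, sire-line cross, terminal product)
and *stock* classes (sex, age-in-service 1..y). Multiplier tiers hold
stock only — their animals are nucleus-born recruits, not a separate
generation.

Timing convention: within a season, stock is recruited (age class 1
from the cohort born the previous season) and aged first, then matings
produce the new cohort. Transmission rows are composed accordingly: the
cohort of tier X places weight 0.5/L on the source cohort (the youngest
parents) and on the source stock ages 1..L−1, per parental side. When a
breed has no multiplier, the cross draws that side fresh from the
nucleus cohort each season (weight 1.0, one season of service) — the
breed's own stock classes serve nucleus matings. Age classes are
equally weighted, i.e. equal class sizes under steady replacement.

**Selection groups.** Four per nucleus (sires/dams of males/females),
two per multiplier (its sires and dams, in the nucleus), two per cross
tier (sire side, dam side). Nucleus-origin groups are cumulative;
multiplier/crossbred-origin groups are non-cumulative: their injected
differential is re-zeroed after one turnover of the receiving tier, so
they contribute a transient offset, never a trend. Whether multiplier
transfers add their own differential on top of the nucleus trend is an
open design choice; the per-pathway differentials default to zero for
all non-nucleus pathways and can be set in the `GainSchedule`.

**Matrices.** `P` is gene transmission plus aging (row-stochastic:
newborn rows split 0.5/0.5 over the parental sides, entry rows recruit
from the source cohort, aging shifts); `Q` is pure aging; `R_j` claims
pathway j's share of its receiving class (0.25 per nucleus group — the
progeny-sex by parental-side quarter of the cohort — and 0.5 per side
elsewhere). The gene-origin recursion m_jt = R_j·n_{t−1} + P·m_{j,t−1},
n_t = Q·n_{t−1} is implemented verbatim; because class sizes are
stationary under constant replacement, gain accumulation uses the
stationary stock-age structure (R_j applied to the all-ones vector) as
the per-season injection. Gene-origin conservation is checked on the
first-gate partition — nucleus-pathway claims at nucleus cohort
production plus an explicit founder residual sum to one for every class
and season at machine precision; downstream pathway attributions
overlap that partition (they re-select already-attributed genes) and
are reported separately.

**Merit propagation.** The extracted sd_jz are *realized cohort gains*
(cohort-to-cohort differences), not per-gate selection differentials,
so the nucleus cohort class is a trend carrier in the merit transition:
it holds its accumulated gain (self-loop) and receives each season's
injection, making the gene-flow nucleus trajectory equal the simulated
one exactly; downstream tiers then lag it through the transmission
rows. The accumulated level of a tier at season t is

    level_X(t) = Σ_j Σ_{z≤t} sd_jz · (P-propagated injection of pathway j, aged t − z),

and the predicted tier mean is its additive cross mean (crossbred mean
= average of parental tier means, recursively; no heterosis) plus that
level. The season-aggregated quantity g (the double sum over pathways
and seasons of injected gains times realized fractions) is also
reported; it is the total expressed gain summed over the horizon, the
natural companion to undiscounted per-season economics.

## Economics

Profit per season = four revenue categories + trait-improvement value −
six cost categories, no discounting. Trait revenue credits the terminal
tier's predicted mean against its season-0 baseline, signed by the
favorable direction, at `econ_value` currency per unit per production
animal.

Headcounts use a steady-state herd structure (no ramp-up), derived from
the system parameters because no standard count bookkeeping exists:

* **Supply mode** (`n_target = 0`): all surplus nucleus females of the
  dam-line breed are transferred; each downstream herd is its
  recruitment rate times its lifetime; production animals are the
  crossbred dam herd times its litter size. A longer dam-line lifetime
  therefore carries a proportionally larger dam herd and more
  production animals.
* **Demand mode** (`n_target > 0`): tier sizes are back-computed from
  the target (dams = target/litter, recruits = herd/lifetime), capped
  by nucleus supply; surplus females and males are sold as breeding
  candidates.

Sire herds are sized from the dam herds they serve at `mate_ratio` dams
per sire (default 10). Crossbred males are finished and sold.

## Optimization

Search variables are the downstream lifetimes (yMA, yMB, yMC, yHAB, …)
and nucleus dam counts (nDA, nDB, nDC), all integers with inclusive
bounds; the production target and the nucleus gain schedules are fixed
per run — the nuclei are simulated once, cached, and every evaluation
re-runs only the deterministic gene-flow + economics layers
(milliseconds each).

Surrogate: Gaussian-process regression on inputs scaled to the unit
cube, Matérn-5/2 kernel with per-dimension length scales, a white-noise
floor (1e-10..1e-1), targets standardized, 2 optimizer restarts.
Acquisition: expected improvement, maximized over 1024 random
candidates per proposal; q-point batches by the constant-liar strategy
(lying the incumbent best at each chosen point and refitting), with
proposals deduplicated against the history and each other. Integers are
handled by stratified flooring of unit-cube samples, so a saturated 1-D
integer range enumerates exactly. The initial design is a Latin
hypercube of 2·d points (configurable). The random-search baseline
samples uniformly on the lattice through the identical evaluation and
recording pipeline.

## Test conditions and problem sizes

The test suite validates the machinery at desk scale, chosen so the
full suite runs in a few minutes on one core:

* gene-flow vs brute-force equivalence: 3 nuclei of 12 dams/3 sires,
  litter 6, accuracy-mode EBVs (the evaluation method is immaterial to
  the gene-flow algebra), 5 seasons, 200 paired replicates, agreement
  within 3 Monte-Carlo standard errors;
* design orderings: 24-dam nuclei, pedigree BLUP, 50 replicates;
* optimizer validation: a separable concave synthetic profit with known
  optimum over the 7-variable structure space, 20 seeds, 10 iterations
  of 5 proposals against an equal-budget random search (sign test).

The brute-force oracle samples multiplier recruits uniformly from their
source cohort — the same representativeness assumption the
deterministic model makes. The small distortion from removing nucleus
replacements before transfer is ignored at these herd sizes; with very
small nuclei and heavy within-cohort selection the deterministic
prediction would be slightly optimistic for downstream tiers.

Passing these tests shows the algebra, bookkeeping and orderings are
right under the stated assumptions. It does not calibrate the economics
to any market, model heterosis or maternal effects, or validate the
infinitesimal model against locus-level genetic architectures.

## Known limitations

* Purely additive predictions: no heterosis or dominance, so crossbred
  means are parental averages; no maternal-effect partitioning.
* Single breeding-goal trait drives selection (multiple traits parse
  but only the first is optimized).
* No genomic data model; marker-based evaluation enters only through
  the accuracy parameter. No inbreeding-avoidance or genomic mating.
* Steady-state headcounts (no transition dynamics after a structure
  change); no net-present-value discounting by design.
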