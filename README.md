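# crossplan

Design, evaluate and optimize animal breeding programs that combine
pure-bred nucleus herds with multi-tier crossbreeding systems (the
nucleus → multiplier → crossbred dam line → terminal product pyramid
used in pig and poultry production).

Everything is driven by a single TOML parameter file and exposed both as
a Python library and as a CLI with three workflows:

| command     | what it does |
|-------------|--------------|
| `run-core`  | Stochastic simulation of one nucleus herd with overlapping generations: within-litter preselection, EBV estimation (pedigree BLUP or an accuracy-parameterized pseudo-EBV), truncation selection, age-based culling. Reports genetic gain, inbreeding increase and genetic-variance change per season. |
| `run-whole` | Deterministic prediction of crossbred performance by the gene-flow method, fed with per-season gains extracted from the nucleus simulations, plus per-season economic profit of the whole system. |
| `run-opt`   | Bayesian optimization (Gaussian-process surrogate, expected improvement) of the downstream population structure: tier productive lifetimes and nucleus dam counts, at a fixed production target and fixed nucleus gains. |

## The models

**Nucleus.** Animals follow the infinitesimal model: an offspring's true
breeding value is the parental midpoint plus a Mendelian-sampling
deviation with variance ½σ²ₐ(1 − (F_s + F_d)/2). Inbreeding
coefficients come from the Meuwissen–Luo pedigree recursion; pedigree
BLUP solves the single-trait animal-model mixed-model equations with
λ = (1 − h²)/h² and A⁻¹ assembled by Henderson's rules. Selection is
truncation on EBV within sex, honoring the trait's favorable direction
(e.g. days to market weight: lower is better).

**Gene flow.** Each tier is a set of state classes — a newborn cohort
plus (sex, age-in-service) breeding-stock classes. A transmission matrix
**P** routes half of every newborn cohort's genes from the sire-source
classes and half from the dam-source classes and ages the stock; an
aging matrix **Q** tracks the initial stock washing out; replacement
matrices **R_j** attribute each season's recruitment to its selection
pathway. The system decomposes into sex-by-ancestry selection groups
(4 per nucleus, 2 per multiplier, 2 per cross tier — 22 in the classic
fully-multiplied 3-way system); nucleus-origin groups accumulate
response, multiplier/crossbred-origin groups carry only transient
differentials. Realized per-season nucleus gains sd_jz are injected
through the pathways and propagated, so the predicted mean of tier X at
season t is its additive cross mean plus the accumulated, lagged gain.

**Economics.** Six cost categories (rearing, dam/sire maintenance,
fixed per-season, phenotyping, genotyping) against four revenue
categories (production animals, culls, sold female/male candidates)
plus the value of trait improvement, itemized per season with no
discounting.

## Worked example

```bash
crossplan make-config --kind whole_3way --seed 1 -o example.toml
crossplan run-whole --config example.toml --out demo
```

prints (seed 1):

```json
{
  "terminal_tier": "H_ABC",
  "terminal_initial_mean": 167.5,
  "terminal_final_mean": 160.49,
  "profit_total": 6657678.07,
  "profit_per_season": 1331535.61,
  "nuclei": {
    "A": {"relative_genetic_progress": 0.4648, "inbreeding_increment": 0.1289, ...}
  }
}
```

The three breeds start the AGE trait at 180/170/160 days, so the
terminal cross H_ABC opens at ½·160 + ¼·180 + ¼·170 = 167.5 days.
Over five breeding seasons the nucleus gains flow down the pyramid with
the genetic lag set by the tier lifetimes, taking the production animals
to 160.5 days; `demo/whole_phenotypes.csv` holds the full per-tier
trajectory and `demo/profit_seasons.csv` the itemized season ledgers.
`relative_genetic_progress` is each nucleus's total favorable gain per
initial genetic standard deviation per season.

The same parameter file drives the other two commands:

```bash
crossplan run-core --config example.toml --out core   # one nucleus only
crossplan run-opt  --config example.toml --out opt    # needs [optimize.bounds]
```

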