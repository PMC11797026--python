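"""Brute-force animal-level simulation of a 3-way crossbreeding system.

Independent oracle for the deterministic gene-flow prediction: every
tier is simulated animal by animal (multiplier recruitment, stock aging,
random mating, Mendelian sampling), and the terminal cohort's mean
breeding value is recorded per season.  Only the nucleus simulation is
shared with the package (it generates the gain schedules both sides
consume); everything downstream is re-implemented here from first
principles.

Timing mirrors the gene-flow convention: each season stock is first
recruited (age-class 1 from the cohort born the previous season) and
aged, then matings produce the new cohort.  Multiplier recruits are a
uniform random sample of their source cohort.
"""

from __future__ import annotations

import numpy as np

from crossplan.config import CrossSystemSpec, NucleusSpec, TraitSpec
from crossplan.nucleus import found_population, simulate_season


class _Stock:
    """Equal-sized age classes of breeding animals (their TBVs)."""

    def __init__(self, lifetime: int, per_age: int, init_sd: float,
                 rng: np.random.Generator):
        self.lifetime = lifetime
        self.per_age = per_age
        self.ages: list[np.ndarray] = [
            rng.normal(0.0, init_sd, per_age) for _ in range(lifetime)
        ]

    def pool(self) -> np.ndarray:
        return np.concatenate(self.ages)

    def turn_over(self, recruits: np.ndarray) -> None:
        self.ages = [recruits] + self.ages[: self.lifetime - 1]


def _sample(rng, values: np.ndarray, k: int) -> np.ndarray:
    idx = rng.choice(len(values), size=k, replace=len(values) < k)
    return values[idx]


def simulate_three_way(
    spec: NucleusSpec,
    trait: TraitSpec,
    system: CrossSystemSpec,
    n_seasons: int,
    seed: int,
    per_age: int = 10,
    n_off: int = 40,
):
    """One replicate.  Returns (per-breed delta_g arrays, terminal cohort
    mean TBV deviations for seasons 1..n_seasons)."""
    rng = np.random.default_rng(seed)
    sd0 = trait.sigma_a
    var_a = trait.var_a

    # nuclei: package simulation, one pedigree per breed
    peds = {}
    prev = {}
    cohorts = {}          # breed -> {season: (tbv array, sex array)}
    deltas = {b: [] for b in system.breeds}
    for b in system.breeds:
        peds[b] = found_population(spec, trait, rng)
        prev[b] = float(np.mean([t[0] for t in peds[b].tbv]))
        cohorts[b] = {0: (np.array([t[0] for t in peds[b].tbv]),
                          np.array(peds[b].sex))}

    L = {t: system.lifetime(t, 2) for t in ("M_A", "M_B", "M_C", "H_AB")}
    m_a = _Stock(L["M_A"], per_age, sd0, rng)   # females of breed A
    m_b = _Stock(L["M_B"], per_age, sd0, rng)   # males of breed B
    m_c = _Stock(L["M_C"], per_age, sd0, rng)   # males of breed C
    hab = _Stock(L["H_AB"], per_age, sd0, rng)  # crossbred females
    hab_cohort_prev = rng.normal(0.0, sd0, n_off)

    terminal_means = np.zeros(n_seasons + 1)

    for season in range(1, n_seasons + 1):
        # nuclei advance; record the full birth cohort
        for b in system.breeds:
            ped = peds[b]
            summ = simulate_season(ped, spec, trait, season, rng, prev[b])
            deltas[b].append(summ.delta_g)
            prev[b] = summ.mean_tbv
            born = [i for i in range(len(ped))
                    if ped.birth_season[i] == season]
            cohorts[b][season] = (
                np.array([ped.tbv[i][0] for i in born]),
                np.array([ped.sex[i] for i in born]),
            )

        # recruit and age downstream stock from last season's cohorts
        def nucleus_recruits(breed: str, sex_code: int) -> np.ndarray:
            tbv, sex = cohorts[breed][season - 1]
            pool = tbv[sex == sex_code]
            return _sample(rng, pool if pool.size else tbv, per_age)

        m_a.turn_over(nucleus_recruits("A", 1))   # females
        m_b.turn_over(nucleus_recruits("B", 0))   # males
        m_c.turn_over(nucleus_recruits("C", 0))
        hab.turn_over(_sample(rng, hab_cohort_prev, per_age))

        # matings produce this season's cohorts
        def cross(sires: np.ndarray, dams: np.ndarray) -> np.ndarray:
            s = _sample(rng, sires, n_off)
            d = _sample(rng, dams, n_off)
            return 0.5 * (s + d) + rng.normal(0, np.sqrt(var_a / 2), n_off)

        hab_cohort = cross(m_b.pool(), m_a.pool())
        terminal_cohort = cross(m_c.pool(), hab.pool())
        hab_cohort_prev = hab_cohort
        terminal_means[season] = float(terminal_cohort.mean())

    return {b: np.array(d) for b, d in deltas.items()}, terminal_means
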