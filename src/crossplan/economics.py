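"""Per-season economic evaluation of a breeding system.

Profit is itemized per season with no discounting: six cost categories
(rearing, dam maintenance, sire maintenance, a fixed per-season cost,
phenotyping, genotyping) against four revenue categories (production
animals, culled breeding stock, sold female and male breeding
candidates) plus the economic value of trait improvement in the
production animals relative to the season-0 baseline.

Headcounts per tier are derived from the system structure.  Two modes:

* supply-driven (``n_target == 0``): the nucleus feeds every downstream
  tier with all surplus females; herd sizes are recruitment rate times
  productive lifetime, so a longer dam-line lifetime carries more
  production animals.
* demand-driven (``n_target > 0``): tier sizes are back-computed from
  the target production count (dams = target / litter size, recruits =
  herd / lifetime); surplus candidates are sold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CrossSystemSpec, EconomicModel, NucleusSpec, TraitSpec


@dataclass
class SeasonCounts:
    """Animal flows of one breeding season (steady-state herd structure)."""

    production: float = 0.0
    culled: float = 0.0
    sold_female: float = 0.0
    sold_male: float = 0.0
    dams: float = 0.0
    sires: float = 0.0
    phenotyped: float = 0.0
    genotyped: float = 0.0
    reared: float = 0.0

    def validate(self) -> None:
        for k, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"count {k} is negative: {v}")


@dataclass
class SeasonLedger:
    season: int
    counts: SeasonCounts
    costs: dict[str, float]
    revenues: dict[str, float]
    profit: float


def derive_counts(
    system: CrossSystemSpec,
    nuclei: dict[str, NucleusSpec],
) -> SeasonCounts:
    """Steady-state per-season headcounts of the whole pyramid.

    The dam line flows downward: surplus nucleus females recruit the
    top-breed multiplier, multiplier litters supply crossbred dams, and
    crossbred dams farrow the production animals.  Sire herds are sized
    from the dam herds they serve (``mate_ratio`` dams per sire).  With a
    production target the dam line is instead back-computed from the
    target and surpluses are sold as breeding candidates.
    """
    b = system.breeds
    demand = system.n_target > 0
    cohort = {x: nuclei[x].n_dams * nuclei[x].litter_size for x in b}
    repl_f = {x: nuclei[x].n_dams / nuclei[x].y_dam for x in b}
    repl_m = {x: nuclei[x].n_sires / nuclei[x].y_sire for x in b}

    dams = sum(float(nuclei[x].n_dams) for x in b)
    sires = sum(float(nuclei[x].n_sires) for x in b)
    culled = sum(repl_f.values()) + sum(repl_m.values())
    reared = float(sum(cohort.values()))
    phenotyped = float(sum(nuclei[x].n_dams * nuclei[x].nfam for x in b))
    genotyped = float(sum(
        nuclei[x].n_dams * nuclei[x].nfam
        for x in b if nuclei[x].ebv_method == "accuracy"
    ))
    surplus_f = {x: max(0.5 * cohort[x] - repl_f[x], 0.0) for x in b}
    surplus_m = {x: max(0.5 * cohort[x] - repl_m[x], 0.0) for x in b}

    sold_f = sold_m = production = 0.0

    def life(tier: str) -> float:
        return float(system.lifetime(tier, 2))

    def litter(tier: str) -> float:
        return float(system.litter_size(tier, 8))

    def mult_life(breed: str) -> float:
        """Service seasons of breed's animals in their crossing role."""
        return life(f"M_{breed}") if system.has_multiplier(breed) else 1.0

    if system.n_way == 1:
        sold_f += surplus_f[b[0]]
        sold_m += surplus_m[b[0]]
        c = SeasonCounts(production, culled, sold_f, sold_m, dams, sires,
                         phenotyped, genotyped, reared)
        c.validate()
        return c

    dam_top = b[0]
    terminal = system.terminal_tier
    cross_dam_tier = f"H_{b[0]}{b[1]}" if system.n_way >= 3 else None

    # --- dam-line chain ----------------------------------------------------
    if not demand:
        # supply mode: every surplus top-breed female is transferred
        m_rec = surplus_f[dam_top]
        m_dams = m_rec * mult_life(dam_top)
        if cross_dam_tier is None:
            cross_dams = 0.0
            cohort_cross = 0.0
            production = m_dams * litter(terminal)
        else:
            cohort_cross = m_dams * litter(cross_dam_tier)
            cross_rec = 0.5 * cohort_cross      # all crossbred females retained
            cross_dams = cross_rec * life(cross_dam_tier)
            production = cross_dams * litter(terminal)
            sold_m += 0.5 * cohort_cross        # crossbred males finished/sold
    else:
        # demand mode: back-compute needs, cap by nucleus supply, sell spares
        target = float(system.n_target)
        if cross_dam_tier is None:
            m_dams_need = target / litter(terminal)
            m_rec_need = m_dams_need / mult_life(dam_top)
        else:
            cross_dams_need = target / litter(terminal)
            cross_rec_need = cross_dams_need / life(cross_dam_tier)
            cohort_cross_need = 2.0 * cross_rec_need
            m_dams_need = cohort_cross_need / litter(cross_dam_tier)
            m_rec_need = m_dams_need / mult_life(dam_top)
        scale = min(1.0, surplus_f[dam_top] / m_rec_need) if m_rec_need > 0 else 1.0
        m_rec = m_rec_need * scale
        m_dams = m_dams_need * scale
        sold_f += surplus_f[dam_top] - m_rec
        if cross_dam_tier is None:
            cross_dams = 0.0
            cohort_cross = 0.0
            production = m_dams * litter(terminal)
        else:
            cohort_cross = m_dams * litter(cross_dam_tier)
            cross_rec = cross_rec_need * scale
            cross_dams = cross_dams_need * scale
            production = cross_dams * litter(terminal)
            sold_f += max(0.5 * cohort_cross - cross_rec, 0.0)
            sold_m += 0.5 * cohort_cross

    dams += m_dams + cross_dams
    culled += m_rec + (cross_dams / life(cross_dam_tier) if cross_dam_tier else 0.0)
    reared += cohort_cross + production

    # --- sire side: herds sized by the dam herds they serve ----------------
    def add_sire_herd(breed: str, dams_served: float) -> None:
        nonlocal sires, culled
        n = dams_served / system.mate_ratio
        rec = n / mult_life(breed)
        sires += n
        culled += rec
        surplus_m[breed] = max(surplus_m[breed] - rec, 0.0)

    add_sire_herd(b[1], m_dams)                       # sires of the first cross
    if system.n_way == 3:
        add_sire_herd(b[2], cross_dams)               # terminal sires
    elif system.n_way == 4:
        hcd = f"H_{b[2]}{b[3]}"
        n_term_sires = cross_dams / system.mate_ratio
        hcd_rec = n_term_sires / life(hcd)
        hcd_cohort = 2.0 * hcd_rec
        d_dams = hcd_cohort / litter(hcd)
        sires += n_term_sires
        dams += d_dams
        culled += hcd_rec + d_dams / mult_life(b[3])
        reared += hcd_cohort
        sold_m += 0.5 * hcd_cohort - hcd_rec if 0.5 * hcd_cohort > hcd_rec else 0.0
        add_sire_herd(b[2], d_dams)

    # remaining nucleus surpluses are sold as breeding candidates
    for breed in b[1:]:
        sold_f += surplus_f[breed]
    sold_m += sum(surplus_m.values())

    c = SeasonCounts(production, culled, sold_f, sold_m, dams, sires,
                     phenotyped, genotyped, reared)
    c.validate()
    return c


def season_profit(
    season: int,
    counts: SeasonCounts,
    econ: EconomicModel,
    traits: dict[str, TraitSpec] | None = None,
    predicted_means: dict[str, float] | None = None,
    baseline_means: dict[str, float] | None = None,
) -> SeasonLedger:
    """Itemized profit of one season: revenues minus costs, no discounting.

    Trait revenue credits improvement of the production animals'
    predicted mean over the season-0 baseline, signed by the trait's
    favorable direction, at ``econ_value`` per unit per head.
    """
    counts.validate()
    costs = {
        "rearing": econ.cost_rearing_per_head * counts.reared,
        "dam_maintenance": econ.cost_dam_maintenance * counts.dams,
        "sire_maintenance": econ.cost_sire_maintenance * counts.sires,
        "extra": econ.cost_extra_per_season,
        "phenotyping": econ.cost_phenotyping_per_head * counts.phenotyped,
        "genotyping": econ.cost_genotyping_per_head * counts.genotyped,
    }
    revenues = {
        "production": econ.rev_production_per_head * counts.production,
        "culls": econ.rev_cull_per_head * counts.culled,
        "female_candidates": econ.rev_female_candidate * counts.sold_female,
        "male_candidates": econ.rev_male_candidate * counts.sold_male,
        "trait_improvement": 0.0,
    }
    if traits and predicted_means and baseline_means:
        gain_rev = 0.0
        for name, tr in traits.items():
            if name not in predicted_means:
                continue
            improvement = tr.favorable_sign() * (
                predicted_means[name] - baseline_means[name]
            )
            gain_rev += tr.econ_value * improvement * counts.production
        revenues["trait_improvement"] = gain_rev
    profit = sum(revenues.values()) - sum(costs.values())
    return SeasonLedger(season=season, counts=counts, costs=costs,
                        revenues=revenues, profit=profit)


@dataclass
class ProfitSummary:
    total: float
    per_season_mean: float
    n_seasons: int


def aggregate_profit(ledgers: list[SeasonLedger]) -> ProfitSummary:
    """Arithmetic total and mean over seasons (no discount factors)."""
    if not ledgers:
        raise ValueError("need at least one season ledger")
    profits = [l.profit for l in ledgers]
    return ProfitSummary(
        total=float(np.sum(profits)),
        per_season_mean=float(np.mean(profits)),
        n_seasons=len(profits),
    )


def ledgers_frame(ledgers: list[SeasonLedger]) -> pd.DataFrame:
    rows = []
    for l in ledgers:
        row = {"season": l.season, "profit": l.profit}
        row.update({f"cost_{k}": v for k, v in l.costs.items()})
        row.update({f"rev_{k}": v for k, v in l.revenues.items()})
        rows.append(row)
    return pd.DataFrame(rows)
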