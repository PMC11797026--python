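"""Whole-system evaluation: nuclei -> gene flow -> economics.

``run_whole`` simulates every nucleus stochastically (replicated),
extracts the across-replicate mean per-season genetic gains into a
:class:`~crossplan.geneflow.GainSchedule`, propagates them through the
deterministic gene-flow engine to predict every tier's phenotype
trajectory, derives steady-state tier headcounts, and prices each season
with the economic model.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, CrossSystemSpec, ProgramConfig
from .economics import (SeasonLedger, aggregate_profit, derive_counts,
                        season_profit, ProfitSummary)
from .geneflow import (GainAccumulation, GainSchedule, PhenotypeTrajectory,
                       accumulate_gain, build_matrices, build_selection_groups,
                       predict_phenotype)
from .nucleus import CoreReport, run_core


def effective_system(config: ProgramConfig) -> CrossSystemSpec:
    """The system spec with nucleus stock lifetimes filled in from the
    nucleus sections (gene-flow state classes need them)."""
    if config.system is None:
        raise ConfigError("config has no [system] section")
    sys = copy.deepcopy(config.system)
    for b in sys.breeds:
        spec = config.nuclei[b]
        # one entry per nucleus tier; sexes share the max service time for
        # the origin bookkeeping (merit propagation does not use it)
        sys.tier_lifetimes.setdefault(f"N_{b}", max(spec.y_dam, spec.y_sire))
    sys.n_seasons = config.run.n_seasons
    return sys


@dataclass
class WholeReport:
    """Everything ``run_whole`` computes for one parameter set."""

    config: ProgramConfig
    system: CrossSystemSpec
    nucleus_reports: dict[str, CoreReport]
    schedule: GainSchedule
    accumulation: GainAccumulation
    trajectory: PhenotypeTrajectory
    ledgers: list[SeasonLedger]
    profit: ProfitSummary

    @property
    def terminal_tier(self) -> str:
        return self.system.terminal_tier

    def terminal_trajectory(self) -> np.ndarray:
        return self.trajectory.tier(self.terminal_tier)

    def summary_dict(self) -> dict:
        return {
            "terminal_tier": self.terminal_tier,
            "terminal_initial_mean": self.trajectory.initial[self.terminal_tier],
            "terminal_final_mean": float(self.terminal_trajectory()[-1]),
            "profit_total": self.profit.total,
            "profit_per_season": self.profit.per_season_mean,
            "nuclei": {b: r.summary_dict() for b, r in
                       self.nucleus_reports.items()},
        }


def extract_gain_schedule(
    config: ProgramConfig,
    nucleus_reports: dict[str, CoreReport],
):
    """Across-replicate mean per-season gain of each nucleus, routed to
    its four selection pathways.  The per-breed sums equal the simulated
    total gains exactly (telescoping cohort means)."""
    system = effective_system(config)
    groups = build_selection_groups(system)
    matrices = build_matrices(system, groups)
    per_breed = {b: rep.mean_delta_g() for b, rep in nucleus_reports.items()}
    schedule = GainSchedule.from_nucleus_gains(
        matrices, per_breed, trait_names=[config.objective_trait.name]
    )
    return matrices, schedule


def run_whole(
    config: ProgramConfig,
    nucleus_reports: dict[str, CoreReport] | None = None,
) -> WholeReport:
    """Evaluate a full crossbreeding system.

    ``nucleus_reports`` may carry pre-simulated nuclei (the optimizer
    reuses one simulation across many structure evaluations, since the
    nucleus gains are fixed while downstream structure varies).
    """
    system = effective_system(config)
    trait = config.objective_trait
    if nucleus_reports is None:
        nucleus_reports = {
            b: run_core(config, breed=b) for b in system.breeds
        }
    matrices, schedule = extract_gain_schedule(config, nucleus_reports)
    acc = accumulate_gain(schedule, matrices)
    traj = predict_phenotype(
        system, trait.initial_mean_per_breed, acc, trait.name
    )

    counts = derive_counts(system, {b: config.nuclei[b] for b in system.breeds})
    terminal = system.terminal_tier
    baseline = {trait.name: traj.initial[terminal]}
    ledgers = []
    for season in range(1, config.run.n_seasons + 1):
        predicted = {trait.name: float(traj.tier(terminal)[season])}
        ledgers.append(
            season_profit(
                season, counts, config.economics,
                traits={trait.name: trait},
                predicted_means=predicted,
                baseline_means=baseline,
            )
        )
    return WholeReport(
        config=config,
        system=system,
        nucleus_reports=nucleus_reports,
        schedule=schedule,
        accumulation=acc,
        trajectory=traj,
        ledgers=ledgers,
        profit=aggregate_profit(ledgers),
    )


# ---------------------------------------------------------------------------
# scheme comparison
# ---------------------------------------------------------------------------

#: config attributes a comparison grid may vary
_DECLARABLE = ("tier_lifetimes", "n_dams", "n_target", "multipliers")


def _comparison_key(config: ProgramConfig) -> dict:
    """Everything that must be identical across compared schemes."""
    from .config import config_to_dict

    raw = config_to_dict(config)
    if "system" in raw:
        raw["system"].pop("tier_lifetimes", None)
        raw["system"].pop("n_target", None)
        raw["system"].pop("multipliers", None)
    for sec in raw.get("nucleus", {}).values():
        sec.pop("n_dams", None)
    return raw


def compare_schemes(
    configs: list[ProgramConfig],
    labels: list[dict] | None = None,
    nucleus_reports: dict[str, CoreReport] | None = None,
) -> pd.DataFrame:
    """Evaluate several schemes differing only in declared structure
    variables (tier lifetimes, nucleus dam counts, multiplier flags,
    production target) and rank them.

    Returns one row per scheme with the varied parameters, the terminal
    tier's final predicted mean, and total / per-season profit, sorted by
    per-season profit (best first).
    """
    if len(configs) < 2:
        raise ValueError("need at least two schemes to compare")
    ref = _comparison_key(configs[0])
    for c in configs[1:]:
        if _comparison_key(c) != ref:
            raise ValueError(
                "schemes differ in parameters outside the declared "
                f"comparison variables {_DECLARABLE}"
            )
    rows = []
    for i, c in enumerate(configs):
        rep = run_whole(c, nucleus_reports=nucleus_reports)
        row = dict(labels[i]) if labels else {}
        row.update(
            {
                "final_phenotype": float(rep.terminal_trajectory()[-1]),
                "profit_total": rep.profit.total,
                "profit_per_season": rep.profit.per_season_mean,
            }
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("profit_per_season", ascending=False).reset_index(
        drop=True
    )
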