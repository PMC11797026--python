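"""Parameter-file handling.

A whole breeding program -- trait genetics, nucleus structure, the
crossbreeding system topology, economics and optimizer settings -- is
driven by a single TOML parameter file.  This module parses and validates
that file, serializes configs back to text, and builds tiny deterministic
fixture configs for tests and examples.

Sections of the parameter file::

    [global]            seed, replicates, n_seasons, out_dir, threads
    [trait.NAME]        h2, var_a, econ_value, direction, [trait.NAME.initial_mean]
    [nucleus.BREED]     n_dams, n_sires, litter_size, nfam, y_dam, y_sire,
                        ebv_method ("pblup" | "accuracy"), accuracy
    [system]            n_way, breeds, multipliers, n_target, mate_ratio,
                        [system.tier_lifetimes], [system.tier_litter_sizes]
    [economics]         six cost rates and four revenue rates
    [optimize]          iterations, proposals, initial_points, [optimize.bounds]

All counts are per breeding season; one "season" is the unit of time
throughout (a litter per dam per season, lifetimes in seasons).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any


class ConfigError(ValueError):
    """A missing mandatory key or an invariant violation in a parameter file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_DIRECTIONS = ("lower_is_better", "higher_is_better")
_EBV_METHODS = ("pblup", "accuracy")


@dataclass
class TraitSpec:
    """A single trait under selection.

    h2 is the narrow-sense heritability, var_a the additive genetic
    variance (trait units squared), econ_value the currency return of a
    one-unit improvement in the favorable direction, and
    initial_mean_per_breed the starting population mean of each breed.
    """

    name: str
    h2: float
    var_a: float
    initial_mean_per_breed: dict[str, float]
    econ_value: float = 0.0
    direction: str = "higher_is_better"

    def validate(self, breeds: list[str] | None = None) -> None:
        if not (0.0 < self.h2 <= 1.0):
            raise ConfigError(f"trait.{self.name}.h2 must be in (0, 1], got {self.h2}")
        if self.var_a < 0.0:
            raise ConfigError(f"trait.{self.name}.var_a must be >= 0, got {self.var_a}")
        if self.direction not in _DIRECTIONS:
            raise ConfigError(
                f"trait.{self.name}.direction must be one of {_DIRECTIONS}"
            )
        for b in breeds or []:
            if b not in self.initial_mean_per_breed:
                raise ConfigError(
                    f"trait.{self.name}.initial_mean is missing breed {b!r}"
                )

    @property
    def sigma_a(self) -> float:
        return self.var_a**0.5

    @property
    def var_e(self) -> float:
        """Residual variance implied by h2 = var_a / (var_a + var_e)."""
        return self.var_a * (1.0 - self.h2) / self.h2

    def favorable_sign(self) -> float:
        """+1 if larger trait values are better, -1 if smaller are better."""
        return -1.0 if self.direction == "lower_is_better" else 1.0


@dataclass
class NucleusSpec:
    """Structure of one pure-bred nucleus herd."""

    breed: str
    n_dams: int
    n_sires: int
    litter_size: int
    nfam: int
    y_dam: int = 2
    y_sire: int = 2
    ebv_method: str = "pblup"
    accuracy: float = 0.7

    def validate(self) -> None:
        if self.n_dams < 1 or self.n_sires < 1:
            raise ConfigError(f"nucleus.{self.breed}: need at least 1 dam and 1 sire")
        if self.n_sires > self.n_dams:
            raise ConfigError(
                f"nucleus.{self.breed}: n_sires ({self.n_sires}) must not exceed "
                f"n_dams ({self.n_dams})"
            )
        if self.litter_size < 1:
            raise ConfigError(f"nucleus.{self.breed}.litter_size must be >= 1")
        if not (1 <= self.nfam <= self.litter_size):
            raise ConfigError(
                f"nucleus.{self.breed}.nfam must satisfy 1 <= nfam <= litter_size "
                f"({self.litter_size}), got {self.nfam}"
            )
        if self.y_dam < 1 or self.y_sire < 1:
            raise ConfigError(f"nucleus.{self.breed}: productive lifetimes must be >= 1")
        if self.ebv_method not in _EBV_METHODS:
            raise ConfigError(
                f"nucleus.{self.breed}.ebv_method must be one of {_EBV_METHODS}"
            )
        if not (0.0 <= self.accuracy <= 1.0):
            raise ConfigError(f"nucleus.{self.breed}.accuracy must be in [0, 1]")


@dataclass
class CrossSystemSpec:
    """Topology of a 2-/3-/4-way crossbreeding system.

    ``breeds`` is ordered; in a 3-way system [A, B, C], H_AB is the
    crossbred dam line (dams from breed A, sires from breed B) and the
    terminal tier H_ABC crosses breed-C sires onto H_AB dams.  In a 4-way
    system H_AB is the dam line and H_CD the sire line.
    ``multiplier_flags[b]`` says whether breed b has a multiplier tier
    between its nucleus and the crossing step.  ``n_target`` is the
    desired number of terminal production animals per season (0 means
    supply-driven: produce whatever the pyramid sustains).
    """

    n_way: int
    breeds: list[str]
    multiplier_flags: dict[str, bool] = field(default_factory=dict)
    tier_lifetimes: dict[str, int] = field(default_factory=dict)
    tier_litter_sizes: dict[str, int] = field(default_factory=dict)
    n_target: int = 0
    n_seasons: int = 10
    mate_ratio: int = 10

    def validate(self) -> None:
        if self.n_way not in (1, 2, 3, 4):
            raise ConfigError(f"system.n_way must be 2, 3 or 4, got {self.n_way}")
        if len(self.breeds) != self.n_way:
            raise ConfigError(
                f"system.breeds must list exactly n_way={self.n_way} breeds, "
                f"got {self.breeds}"
            )
        if len(set(self.breeds)) != len(self.breeds):
            raise ConfigError("system.breeds must be distinct")
        for b in self.multiplier_flags:
            if b not in self.breeds:
                raise ConfigError(f"system.multipliers names unknown breed {b!r}")
        for tier, y in self.tier_lifetimes.items():
            if y < 1:
                raise ConfigError(
                    f"system.tier_lifetimes.{tier} must be >= 1, got {y}"
                )
        for tier, ls in self.tier_litter_sizes.items():
            if ls < 1:
                raise ConfigError(
                    f"system.tier_litter_sizes.{tier} must be >= 1, got {ls}"
                )
        if self.n_target < 0:
            raise ConfigError("system.n_target must be >= 0")
        if self.n_seasons < 1:
            raise ConfigError("system.n_seasons must be >= 1")
        if self.mate_ratio < 1:
            raise ConfigError("system.mate_ratio must be >= 1")

    def has_multiplier(self, breed: str) -> bool:
        return bool(self.multiplier_flags.get(breed, False))

    def lifetime(self, tier: str, default: int = 2) -> int:
        return int(self.tier_lifetimes.get(tier, default))

    def litter_size(self, tier: str, default: int = 8) -> int:
        return int(self.tier_litter_sizes.get(tier, default))

    @property
    def terminal_tier(self) -> str:
        if self.n_way == 1:
            return f"N_{self.breeds[0]}"
        return "H_" + "".join(self.breeds)


@dataclass
class EconomicModel:
    """Six cost categories and four revenue categories, one currency unit.

    Costs: basic rearing per head, dam and sire maintenance per season,
    a fixed extra cost per season, and phenotyping / genotyping per head.
    Revenues: production animals, culled breeding stock, and sold female /
    male breeding candidates, each per head.
    """

    cost_rearing_per_head: float = 0.0
    cost_dam_maintenance: float = 0.0
    cost_sire_maintenance: float = 0.0
    cost_extra_per_season: float = 0.0
    cost_phenotyping_per_head: float = 0.0
    cost_genotyping_per_head: float = 0.0
    rev_production_per_head: float = 0.0
    rev_cull_per_head: float = 0.0
    rev_female_candidate: float = 0.0
    rev_male_candidate: float = 0.0

    def validate(self) -> None:
        for k, v in asdict(self).items():
            if not isinstance(v, (int, float)) or v != v:  # NaN check
                raise ConfigError(f"economics.{k} must be a finite number")


@dataclass
class RunSettings:
    seed: int = 1
    replicates: int = 5
    threads: int = 1
    n_seasons: int = 10
    out_dir: str = "results"

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("global.replicates must be >= 1")
        if self.n_seasons < 1:
            raise ConfigError("global.n_seasons must be >= 1")


@dataclass
class OptimizeSettings:
    """Search space and budget for structure optimization.

    ``bounds`` maps variable names (yMA, yMB, ..., nDA, nDB, ...) to
    inclusive [lower, upper] integer bounds.
    """

    iterations: int = 10
    proposals: int = 5
    initial_points: int = 0  # 0 -> 2 * n_variables
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.iterations < 1:
            raise ConfigError("optimize.iterations must be >= 1")
        if self.proposals < 1:
            raise ConfigError("optimize.proposals must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ConfigError(f"optimize.bounds.{name}: lower > upper")


@dataclass
class ProgramConfig:
    """A fully parsed and validated parameter set."""

    run: RunSettings
    traits: dict[str, TraitSpec]
    nuclei: dict[str, NucleusSpec]
    system: CrossSystemSpec | None = None
    economics: EconomicModel = field(default_factory=EconomicModel)
    optimize: OptimizeSettings = field(default_factory=OptimizeSettings)

    def validate(self) -> None:
        self.run.validate()
        if not self.traits:
            raise ConfigError("at least one [trait.NAME] section is required")
        breeds = list(self.nuclei)
        for t in self.traits.values():
            t.validate(breeds)
        if not self.nuclei:
            raise ConfigError("at least one [nucleus.BREED] section is required")
        for n in self.nuclei.values():
            n.validate()
        if self.system is not None:
            self.system.validate()
            for b in self.system.breeds:
                if b not in self.nuclei:
                    raise ConfigError(
                        f"system.breeds includes {b!r} but no [nucleus.{b}] section"
                    )
        self.economics.validate()
        self.optimize.validate()

    @property
    def objective_trait(self) -> TraitSpec:
        """The breeding-goal trait (first declared) used for selection."""
        return next(iter(self.traits.values()))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _require(section: dict, key: str, where: str) -> Any:
    if key not in section:
        raise ConfigError(f"missing mandatory key {key!r} in [{where}]")
    return section[key]


def parse_config_dict(raw: dict) -> ProgramConfig:
    """Build and validate a :class:`ProgramConfig` from nested dicts."""
    g = raw.get("global", {})
    run = RunSettings(
        seed=int(g.get("seed", 1)),
        replicates=int(g.get("replicates", 5)),
        threads=int(g.get("threads", 1)),
        n_seasons=int(g.get("n_seasons", 10)),
        out_dir=str(g.get("out_dir", "results")),
    )

    traits: dict[str, TraitSpec] = {}
    for name, sec in raw.get("trait", {}).items():
        where = f"trait.{name}"
        traits[name] = TraitSpec(
            name=name,
            h2=float(_require(sec, "h2", where)),
            var_a=float(_require(sec, "var_a", where)),
            initial_mean_per_breed={
                k: float(v) for k, v in _require(sec, "initial_mean", where).items()
            },
            econ_value=float(sec.get("econ_value", 0.0)),
            direction=str(sec.get("direction", "higher_is_better")),
        )

    nuclei: dict[str, NucleusSpec] = {}
    for breed, sec in raw.get("nucleus", {}).items():
        where = f"nucleus.{breed}"
        nuclei[breed] = NucleusSpec(
            breed=breed,
            n_dams=int(_require(sec, "n_dams", where)),
            n_sires=int(_require(sec, "n_sires", where)),
            litter_size=int(_require(sec, "litter_size", where)),
            nfam=int(_require(sec, "nfam", where)),
            y_dam=int(sec.get("y_dam", 2)),
            y_sire=int(sec.get("y_sire", 2)),
            ebv_method=str(sec.get("ebv_method", "pblup")),
            accuracy=float(sec.get("accuracy", 0.7)),
        )

    system = None
    if "system" in raw:
        sec = raw["system"]
        breeds = [str(b) for b in _require(sec, "breeds", "system")]
        mults = sec.get("multipliers", breeds)
        system = CrossSystemSpec(
            n_way=int(_require(sec, "n_way", "system")),
            breeds=breeds,
            multiplier_flags={b: (b in mults) for b in breeds},
            tier_lifetimes={k: int(v) for k, v in sec.get("tier_lifetimes", {}).items()},
            tier_litter_sizes={
                k: int(v) for k, v in sec.get("tier_litter_sizes", {}).items()
            },
            n_target=int(sec.get("n_target", 0)),
            n_seasons=int(sec.get("n_seasons", run.n_seasons)),
            mate_ratio=int(sec.get("mate_ratio", 10)),
        )

    econ = EconomicModel(**{k: float(v) for k, v in raw.get("economics", {}).items()
                            if k in EconomicModel.__dataclass_fields__})
    unknown = set(raw.get("economics", {})) - set(EconomicModel.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown economics keys: {sorted(unknown)}")

    osec = raw.get("optimize", {})
    opt = OptimizeSettings(
        iterations=int(osec.get("iterations", 10)),
        proposals=int(osec.get("proposals", 5)),
        initial_points=int(osec.get("initial_points", 0)),
        bounds={k: (float(v[0]), float(v[1])) for k, v in osec.get("bounds", {}).items()},
    )

    cfg = ProgramConfig(
        run=run, traits=traits, nuclei=nuclei, system=system,
        economics=econ, optimize=opt,
    )
    cfg.validate()
    return cfg


def parse_config(path: str | Path) -> ProgramConfig:
    """Parse a TOML parameter file into a validated :class:`ProgramConfig`."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return parse_config_dict(raw)


# ---------------------------------------------------------------------------
# serialization (round-trip identity on validated configs)
# ---------------------------------------------------------------------------


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def _emit_table(lines: list[str], header: str, table: dict) -> None:
    sub = {k: v for k, v in table.items() if isinstance(v, dict)}
    flat = {k: v for k, v in table.items() if not isinstance(v, dict)}
    if flat or not sub:
        lines.append(f"[{header}]")
        for k, v in flat.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    for k, v in sub.items():
        _emit_table(lines, f"{header}.{k}", v)


def config_to_dict(cfg: ProgramConfig) -> dict:
    raw: dict[str, Any] = {
        "global": {
            "seed": cfg.run.seed,
            "replicates": cfg.run.replicates,
            "threads": cfg.run.threads,
            "n_seasons": cfg.run.n_seasons,
            "out_dir": cfg.run.out_dir,
        },
        "trait": {
            t.name: {
                "h2": t.h2,
                "var_a": t.var_a,
                "econ_value": t.econ_value,
                "direction": t.direction,
                "initial_mean": dict(t.initial_mean_per_breed),
            }
            for t in cfg.traits.values()
        },
        "nucleus": {
            n.breed: {
                "n_dams": n.n_dams,
                "n_sires": n.n_sires,
                "litter_size": n.litter_size,
                "nfam": n.nfam,
                "y_dam": n.y_dam,
                "y_sire": n.y_sire,
                "ebv_method": n.ebv_method,
                "accuracy": n.accuracy,
            }
            for n in cfg.nuclei.values()
        },
        "economics": asdict(cfg.economics),
        "optimize": {
            "iterations": cfg.optimize.iterations,
            "proposals": cfg.optimize.proposals,
            "initial_points": cfg.optimize.initial_points,
            "bounds": {k: list(v) for k, v in cfg.optimize.bounds.items()},
        },
    }
    if cfg.system is not None:
        s = cfg.system
        raw["system"] = {
            "n_way": s.n_way,
            "breeds": list(s.breeds),
            "multipliers": [b for b in s.breeds if s.multiplier_flags.get(b)],
            "n_target": s.n_target,
            "n_seasons": s.n_seasons,
            "mate_ratio": s.mate_ratio,
            "tier_lifetimes": dict(s.tier_lifetimes),
            "tier_litter_sizes": dict(s.tier_litter_sizes),
        }
    return raw


def serialize_config(cfg: ProgramConfig) -> str:
    """Render a config back to TOML text; parse(serialize(c)) == c."""
    raw = config_to_dict(cfg)
    lines: list[str] = []
    for header in ("global", "trait", "nucleus", "system", "economics", "optimize"):
        if header not in raw:
            continue
        if header in ("trait", "nucleus"):
            for name, table in raw[header].items():
                _emit_table(lines, f"{header}.{name}", table)
        else:
            _emit_table(lines, header, raw[header])
    return "\n".join(lines)


def write_config(cfg: ProgramConfig, path: str | Path) -> None:
    Path(path).write_text(serialize_config(cfg))


# ---------------------------------------------------------------------------
# fixture configs
# ---------------------------------------------------------------------------

_FIXTURE_KINDS = ("core_tiny", "whole_3way", "opt_toy")


def make_fixture_config(kind: str, seed: int = 1) -> ProgramConfig:
    """Deterministic tiny configs used in tests, examples and smoke runs.

    ``core_tiny``  -- a single 20-dam nucleus run for 3 seasons.
    ``whole_3way`` -- a 3-way A/B/C system (initial trait means 180/170/160)
                      with multipliers for all three breeds, 5 seasons.
    ``opt_toy``    -- the 3-way system plus a small optimization search
                      space over tier lifetimes and nucleus dam counts.
    """
    if kind not in _FIXTURE_KINDS:
        raise ConfigError(f"unknown fixture kind {kind!r}; choose from {_FIXTURE_KINDS}")

    base_trait = {
        "h2": 0.35,
        "var_a": 40.0,
        "econ_value": 8.0,
        "direction": "lower_is_better",
    }
    econ = {
        "cost_rearing_per_head": 50.0,
        "cost_dam_maintenance": 200.0,
        "cost_sire_maintenance": 300.0,
        "cost_extra_per_season": 10000.0,
        "cost_phenotyping_per_head": 30.0,
        "cost_genotyping_per_head": 0.0,
        "rev_production_per_head": 300.0,
        "rev_cull_per_head": 500.0,
        "rev_female_candidate": 800.0,
        "rev_male_candidate": 1500.0,
    }

    if kind == "core_tiny":
        raw = {
            "global": {"seed": seed, "replicates": 2, "n_seasons": 3},
            "trait": {"AGE": {**base_trait, "initial_mean": {"A": 180.0}}},
            "nucleus": {
                "A": {
                    "n_dams": 20, "n_sires": 4, "litter_size": 8, "nfam": 4,
                    "y_dam": 2, "y_sire": 2, "ebv_method": "pblup",
                }
            },
            "economics": econ,
        }
        return parse_config_dict(raw)

    nuclei = {
        b: {
            "n_dams": 16, "n_sires": 4, "litter_size": 6, "nfam": 3,
            "y_dam": 2, "y_sire": 2, "ebv_method": "accuracy", "accuracy": 0.7,
        }
        for b in ("A", "B", "C")
    }
    system = {
        "n_way": 3,
        "breeds": ["A", "B", "C"],
        "multipliers": ["A", "B", "C"],
        "n_target": 0,
        "n_seasons": 5,
        "mate_ratio": 10,
        "tier_lifetimes": {"M_A": 2, "M_B": 2, "M_C": 2, "H_AB": 2},
        "tier_litter_sizes": {"H_AB": 6, "H_ABC": 6},
    }
    raw = {
        "global": {"seed": seed, "replicates": 3, "n_seasons": 5},
        "trait": {
            "AGE": {**base_trait, "initial_mean": {"A": 180.0, "B": 170.0, "C": 160.0}}
        },
        "nucleus": nuclei,
        "system": system,
        "economics": econ,
    }
    if kind == "opt_toy":
        raw["system"]["n_target"] = 400
        raw["optimize"] = {
            "iterations": 5,
            "proposals": 3,
            "bounds": {
                "yMA": [2, 6], "yMB": [1, 4], "yMC": [1, 4], "yHAB": [2, 6],
                "nDA": [12, 60], "nDB": [6, 20], "nDC": [6, 20],
            },
        }
    return parse_config_dict(raw)
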