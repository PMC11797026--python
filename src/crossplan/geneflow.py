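"""Deterministic gene-flow prediction for multi-tier crossbreeding systems.

The crossbreeding pyramid (nuclei -> multipliers -> crossbred dam line ->
terminal production animals) is described by state classes: one *cohort*
class per breeding tier (the offspring born that season) and *stock*
classes (tier, sex, age-in-service) for breeding animals.  Genetic merit
and gene origin propagate through square matrices over this state:

* ``P``  -- gene transmission plus aging: newborn-cohort rows draw half
  their genes from the sire-source classes and half from the dam-source
  classes; stock rows shift ages and recruit age-class 1 from the source
  cohort.
* ``Q``  -- pure aging of breeding stock (no recruitment), used to track
  how the initial stock structure washes out.
* ``R_j`` -- the replacement/claim matrix of selection pathway j, routing
  the pathway's selected fraction into its receiving class.

Selection pathways follow the sex-by-ancestry decomposition of the
system: four groups per nucleus (sires/dams of males/females), two per
multiplier (its sires and dams, drawn from the nucleus), and two per
crossbred or terminal tier (sire side and dam side).  Groups whose
parents sit in a nucleus accumulate selection response season after
season; groups whose parents are multiplier or crossbred animals carry
only a transient, non-cumulative differential.

Realized per-season nucleus gains (a :class:`GainSchedule`, typically
extracted from stochastic nucleus simulations) are injected through the
pathway claims and propagated, yielding the predicted phenotype
trajectory of every tier, including the genetic lag created by tier
lifetimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CrossSystemSpec


class TopologyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tiers and topology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TierDef:
    """One population tier and where its parents (or recruits) come from.

    ``sire_source`` / ``dam_source`` name the tier supplying males /
    females for matings that produce this tier's cohort.  Multiplier
    tiers have no cohort of their own: their stock is recruited directly
    from the breed's nucleus cohort (``recruit_source``).
    """

    name: str
    kind: str                     # nucleus | multiplier | crossbred | terminal
    breed: str | None = None
    sire_source: str | None = None
    dam_source: str | None = None
    recruit_source: str | None = None
    stock_sexes: tuple[str, ...] = ()


def build_tiers(system: CrossSystemSpec) -> dict[str, TierDef]:
    """Enumerate the tiers of a 1/2/3/4-way system in topological order."""
    b = system.breeds
    tiers: dict[str, TierDef] = {}
    for breed in b:
        name = f"N_{breed}"
        tiers[name] = TierDef(
            name=name, kind="nucleus", breed=breed,
            sire_source=name, dam_source=name, stock_sexes=("M", "F"),
        )

    def source(breed: str, sex_needed: str) -> str:
        """Multiplier tier if the breed has one, else the nucleus cohort."""
        return f"M_{breed}" if system.has_multiplier(breed) else f"N_{breed}"

    # multipliers: the sex each one supplies depends on its role below
    roles: dict[str, str] = {}
    if system.n_way >= 2:
        roles[b[0]] = "F"                      # dam-line top breed
        roles[b[1]] = "M"                      # sire of the first cross
    if system.n_way == 3:
        roles[b[2]] = "M"                      # terminal sire breed
    if system.n_way == 4:
        roles[b[2]] = "M"                      # sire-line cross: C sires
        roles[b[3]] = "F"                      # D dams
    for breed, sex in roles.items():
        if system.has_multiplier(breed):
            name = f"M_{breed}"
            tiers[name] = TierDef(
                name=name, kind="multiplier", breed=breed,
                recruit_source=f"N_{breed}", stock_sexes=(sex,),
            )

    if system.n_way == 1:
        return tiers
    if system.n_way == 2:
        name = f"H_{b[0]}{b[1]}"
        tiers[name] = TierDef(
            name=name, kind="terminal",
            sire_source=source(b[1], "M"), dam_source=source(b[0], "F"),
        )
        return tiers

    hab = f"H_{b[0]}{b[1]}"
    tiers[hab] = TierDef(
        name=hab, kind="crossbred",
        sire_source=source(b[1], "M"), dam_source=source(b[0], "F"),
        stock_sexes=("F",),
    )
    if system.n_way == 3:
        term = f"H_{b[0]}{b[1]}{b[2]}"
        tiers[term] = TierDef(
            name=term, kind="terminal",
            sire_source=source(b[2], "M"), dam_source=hab,
        )
        return tiers

    hcd = f"H_{b[2]}{b[3]}"
    tiers[hcd] = TierDef(
        name=hcd, kind="crossbred",
        sire_source=source(b[2], "M"), dam_source=source(b[3], "F"),
        stock_sexes=("M",),
    )
    term = f"H_{''.join(b)}"
    tiers[term] = TierDef(
        name=term, kind="terminal", sire_source=hcd, dam_source=hab,
    )
    return tiers


# ---------------------------------------------------------------------------
# selection groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionGroup:
    """One sex-by-ancestry selection pathway."""

    id: str
    tier: str                 # tier whose animals the selection produces
    sex_of_parent: str        # "sire" | "dam"
    sex_of_progeny_class: str  # "M" | "F" | "all"
    origin_tier: str          # tier the selected parents belong to
    cumulative: bool


def build_selection_groups(system: CrossSystemSpec) -> list[SelectionGroup]:
    """Decompose the system into selection groups by sex and ancestry.

    Per nucleus: sires of males, dams of males, sires of females, dams of
    females (4).  Per multiplier: its sires and dams, both in the nucleus
    (2).  Per crossbred/terminal tier: sire side and dam side (2).  The
    classic fully-multiplied 3-way system therefore yields 22 groups, of
    which the nucleus-origin ones are cumulative.
    """
    system.validate()
    tiers = build_tiers(system)
    groups: list[SelectionGroup] = []
    k = 0

    def nxt() -> str:
        nonlocal k
        k += 1
        return f"S{k}"

    for t in tiers.values():
        if t.kind != "nucleus":
            continue
        for progeny in ("M", "F"):
            for parent in ("sire", "dam"):
                groups.append(
                    SelectionGroup(nxt(), t.name, parent, progeny, t.name, True)
                )
    for t in tiers.values():
        if t.kind != "multiplier":
            continue
        for parent in ("sire", "dam"):
            groups.append(
                SelectionGroup(nxt(), t.name, parent, "all", t.recruit_source, True)
            )
    for t in tiers.values():
        if t.kind not in ("crossbred", "terminal"):
            continue
        groups.append(
            SelectionGroup(nxt(), t.name, "sire", "all", t.sire_source, False)
        )
        groups.append(
            SelectionGroup(nxt(), t.name, "dam", "all", t.dam_source, False)
        )
    return groups


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateClass:
    tier: str
    kind: str         # "cohort" | "stock"
    sex: str          # "M" | "F" | "-" for cohorts
    age: int          # 0 for cohorts, 1..lifetime for stock


@dataclass
class GeneFlowMatrices:
    state_index: list[StateClass]
    index: dict[StateClass, int]
    P: np.ndarray                     # gene transmission + aging
    Q: np.ndarray                     # pure aging
    R: dict[str, np.ndarray]          # pathway id -> claim matrix
    T: np.ndarray                     # merit transition (nucleus trend exogenous)
    groups: list[SelectionGroup]
    tiers: dict[str, TierDef]
    system: CrossSystemSpec

    @property
    def n(self) -> int:
        return len(self.state_index)

    def loc(self, tier: str, kind: str, sex: str = "-", age: int = 0) -> int:
        return self.index[StateClass(tier, kind, sex, age)]

    def tier_classes(self, tier: str) -> list[int]:
        return [i for i, c in enumerate(self.state_index) if c.tier == tier]

    def injection(self, group_id: str) -> np.ndarray:
        """Merit-injection vector of a pathway: R_j applied to the
        stationary (all-ones) stock-age structure."""
        return self.R[group_id] @ np.ones(self.n)

    def realization_vector(self, tier: str) -> np.ndarray:
        """Default h vector: the tier's classes, equally weighted."""
        cls = self.tier_classes(tier)
        h = np.zeros(self.n)
        h[cls] = 1.0 / len(cls)
        return h


def _stock_lifetimes(system: CrossSystemSpec, tiers: dict[str, TierDef]) -> dict:
    lifes: dict[tuple[str, str], int] = {}
    for t in tiers.values():
        for sex in t.stock_sexes:
            lifes[(t.name, sex)] = system.lifetime(t.name, 2)
    return lifes


def build_matrices(
    system: CrossSystemSpec, groups: list[SelectionGroup] | None = None
) -> GeneFlowMatrices:
    """Assemble the aging, transmission and replacement matrices.

    Timing convention: within a season, stock is first recruited/aged
    (age-class 1 is filled from the source cohort born the previous
    season), then matings produce the new cohort.  Newborn-cohort rows of
    ``P`` therefore place weight ``0.5/L`` on the source cohort (the
    youngest parents) and on the source stock ages ``1..L-1``.
    """
    if groups is None:
        groups = build_selection_groups(system)
    tiers = build_tiers(system)
    lifes = _stock_lifetimes(system, tiers)
    for (tname, sex), L in lifes.items():
        if L < 1:
            raise TopologyError(f"tier {tname} has lifetime < 1")

    state: list[StateClass] = []
    for t in tiers.values():
        if t.kind != "multiplier":
            state.append(StateClass(t.name, "cohort", "-", 0))
        for sex in t.stock_sexes:
            for age in range(1, lifes[(t.name, sex)] + 1):
                state.append(StateClass(t.name, "stock", sex, age))
    index = {c: i for i, c in enumerate(state)}
    n = len(state)

    def cohort_of(tier_name: str) -> int:
        return index[StateClass(tier_name, "cohort", "-", 0)]

    def parent_side_weights(
        src_tier: str, sex: str, fresh_from_nucleus: bool = False
    ) -> np.ndarray:
        """Composed weights (over state at t-1) of one parental side.

        ``fresh_from_nucleus`` applies when a cross tier draws parents
        from a nucleus directly (the breed has no multiplier): those
        animals come from the newest cohort each season, not from the
        nucleus breeding stock, which is reserved for nucleus matings.
        """
        w = np.zeros(n)
        t = tiers[src_tier]
        if t.kind == "multiplier":
            L = lifes[(src_tier, sex)]
            w[cohort_of(t.recruit_source)] += 1.0 / L
            for age in range(1, L):
                w[index[StateClass(src_tier, "stock", sex, age)]] += 1.0 / L
        elif t.kind == "nucleus" and fresh_from_nucleus:
            w[cohort_of(src_tier)] += 1.0
        elif (src_tier, sex) in lifes:  # nucleus or crossbred stock
            L = lifes[(src_tier, sex)]
            w[cohort_of(src_tier)] += 1.0 / L
            for age in range(1, L):
                w[index[StateClass(src_tier, "stock", sex, age)]] += 1.0 / L
        else:
            w[cohort_of(src_tier)] += 1.0
        return w

    P = np.zeros((n, n))
    T = np.zeros((n, n))
    Q = np.zeros((n, n))

    for t in tiers.values():
        if t.kind != "multiplier":
            r = cohort_of(t.name)
            fresh = t.kind != "nucleus"
            row = 0.5 * parent_side_weights(t.sire_source, "M", fresh) + \
                0.5 * parent_side_weights(t.dam_source, "F", fresh)
            P[r] = row
            if t.kind == "nucleus":
                # merit: the nucleus trend is exogenous (simulated); the
                # cohort class carries the accumulated gain forward
                T[r, r] = 1.0
            else:
                T[r] = row
        for sex in t.stock_sexes:
            L = lifes[(t.name, sex)]
            src = t.recruit_source if t.kind == "multiplier" else t.name
            e1 = index[StateClass(t.name, "stock", sex, 1)]
            P[e1, cohort_of(src)] = 1.0
            T[e1, cohort_of(src)] = 1.0
            for age in range(2, L + 1):
                i = index[StateClass(t.name, "stock", sex, age)]
                j = index[StateClass(t.name, "stock", sex, age - 1)]
                P[i, j] = 1.0
                T[i, j] = 1.0
                Q[i, j] = 1.0

    # replacement / claim matrices
    R: dict[str, np.ndarray] = {}
    for g in groups:
        Rg = np.zeros((n, n))
        tier = tiers[g.tier]
        sex = "M" if g.sex_of_parent == "sire" else "F"
        src = g.origin_tier
        if tier.kind == "nucleus":
            # four groups per nucleus, each claiming a quarter of the
            # cohort (progeny-sex split x parental-side split)
            Rg[cohort_of(g.tier)] = 0.25 * parent_side_weights(src, sex)
        elif tier.kind == "multiplier":
            L = lifes[(g.tier, tier.stock_sexes[0])]
            e1 = index[StateClass(g.tier, "stock", tier.stock_sexes[0], 1)]
            Rg[e1, cohort_of(tier.recruit_source)] = 0.5
        else:  # crossbred / terminal: one parental side of the cohort
            Rg[cohort_of(g.tier)] = 0.5 * parent_side_weights(src, sex, True)
        R[g.id] = Rg

    return GeneFlowMatrices(
        state_index=state, index=index, P=P, Q=Q, R=R, T=T,
        groups=groups, tiers=tiers, system=system,
    )


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


@dataclass
class GeneFlowState:
    """Gene-origin fractions per pathway plus the aging stock vector."""

    m: dict[str, np.ndarray]
    n_vec: np.ndarray
    t: int = 0


def initial_state(matrices: GeneFlowMatrices) -> GeneFlowState:
    n = matrices.n
    m = {g.id: np.zeros(n) for g in matrices.groups}
    n_vec = np.zeros(n)
    for i, c in enumerate(matrices.state_index):
        if c.kind == "stock":
            n_vec[i] = 1.0
    return GeneFlowState(m=m, n_vec=n_vec, t=0)


def propagate(state: GeneFlowState, matrices: GeneFlowMatrices) -> GeneFlowState:
    """One season of the gene-flow recursion:

    ``m_j(t) = R_j n(t-1) + P m_j(t-1)`` and ``n(t) = Q n(t-1)``.
    """
    n = matrices.n
    for j, mj in state.m.items():
        if mj.shape != (n,):
            raise ValueError(f"pathway {j}: state dimension mismatch")
    if state.n_vec.shape != (n,):
        raise ValueError("stock-age vector dimension mismatch")
    new_m = {
        j: matrices.R[j] @ state.n_vec + matrices.P @ mj
        for j, mj in state.m.items()
    }
    return GeneFlowState(m=new_m, n_vec=matrices.Q @ state.n_vec, t=state.t + 1)


def founder_fraction(matrices: GeneFlowMatrices, n_seasons: int) -> np.ndarray:
    """Per-class fraction of genes not yet claimed by any nucleus pathway,
    seasons 0..n_seasons (rows).  Used by the conservation check."""
    n = matrices.n
    out = np.zeros((n_seasons + 1, n))
    f = np.ones(n)
    out[0] = f
    P_part = matrices.P.copy()
    for t in matrices.tiers.values():
        if t.kind == "nucleus":
            P_part[matrices.loc(t.name, "cohort")] = 0.0
    for t in range(1, n_seasons + 1):
        f = P_part @ f
        out[t] = f
    return out


def origin_partition(
    matrices: GeneFlowMatrices, n_seasons: int
) -> dict[str, np.ndarray]:
    """Gene-origin fractions under the first-gate partition.

    Genes are attributed to the nucleus pathway through which they first
    entered the flow (claims happen at nucleus cohort production); the
    remainder is the explicit founder pathway.  For every class and
    season the attributed fractions plus the founder fraction sum to one
    exactly.
    """
    n = matrices.n
    P_part = matrices.P.copy()
    nuc_cohorts = []
    for t in matrices.tiers.values():
        if t.kind == "nucleus":
            r = matrices.loc(t.name, "cohort")
            P_part[r] = 0.0
            nuc_cohorts.append(r)
    nucleus_groups = [g for g in matrices.groups
                      if matrices.tiers[g.tier].kind == "nucleus"]
    out: dict[str, np.ndarray] = {g.id: np.zeros((n_seasons + 1, n))
                                  for g in nucleus_groups}
    out["founder"] = np.zeros((n_seasons + 1, n))
    m = {g.id: np.zeros(n) for g in nucleus_groups}
    f = np.ones(n)
    out["founder"][0] = f
    for t in range(1, n_seasons + 1):
        total_prev = f + sum(m.values())
        new_f = P_part @ f
        new_m = {}
        for g in nucleus_groups:
            r = matrices.loc(g.tier, "cohort")
            claim = np.zeros(n)
            # each of the four groups claims a quarter of the cohort's
            # inflow, whatever its previous attribution
            claim[r] = 0.25 * (matrices.P[r] @ total_prev)
            new_m[g.id] = P_part @ m[g.id] + claim
        f, m = new_f, new_m
        out["founder"][t] = f
        for g in nucleus_groups:
            out[g.id][t] = m[g.id]
    return out


# ---------------------------------------------------------------------------
# gains
# ---------------------------------------------------------------------------


@dataclass
class GainSchedule:
    """Per-pathway, per-season realized genetic gains.

    ``sd[i, j, z]`` is trait i's gain injected through pathway j in
    season z (z = 1..l; column 0 is the pre-simulation baseline and is
    zero).  ``pathway_ids`` orders axis 1; ``traits`` orders axis 0.
    """

    sd: np.ndarray
    pathway_ids: list[str]
    traits: list[str]

    def __post_init__(self):
        if not np.all(np.isfinite(self.sd)):
            raise ValueError("gain schedule contains non-finite values")
        if self.sd.shape[1] != len(self.pathway_ids):
            raise ValueError("gain schedule pathway dimension mismatch")

    @property
    def n_seasons(self) -> int:
        return self.sd.shape[2] - 1

    @classmethod
    def from_nucleus_gains(
        cls,
        matrices: GeneFlowMatrices,
        per_breed_delta: dict[str, np.ndarray],
        trait_names: list[str] | None = None,
    ) -> "GainSchedule":
        """Assign each breed's per-season cohort gains to its four nucleus
        pathways; all other pathways default to zero differential."""
        traits = trait_names or ["trait"]
        deltas = {b: np.atleast_2d(np.asarray(d, float)) for b, d in
                  per_breed_delta.items()}
        l = next(iter(deltas.values())).shape[1]
        k = len(matrices.groups)
        sd = np.zeros((len(traits), k, l + 1))
        for j, g in enumerate(matrices.groups):
            t = matrices.tiers[g.tier]
            if t.kind == "nucleus" and t.breed in deltas:
                sd[:, j, 1:] = deltas[t.breed]
        return cls(sd=sd, pathway_ids=[g.id for g in matrices.groups],
                   traits=traits)


@dataclass
class GainAccumulation:
    """Accumulated genetic progress.

    ``levels[i, t, :]`` is the state-class merit vector of trait i at
    season t (trait units above the starting level).  ``g[(trait, tier)]``
    is the double sum over pathways and seasons of injected gains times
    realized gene fractions -- the season-aggregated expressed progress.
    """

    levels: np.ndarray                       # (n_traits, l+1, n_classes)
    g: dict[tuple[str, str], float]
    traits: list[str]
    matrices: GeneFlowMatrices

    def tier_level(self, trait: str, tier: str) -> np.ndarray:
        """Per-season accumulated gain expressed in a tier (cohort class
        if the tier breeds its own cohort, stock average otherwise)."""
        i = self.traits.index(trait)
        m = self.matrices
        t = m.tiers[tier]
        if t.kind != "multiplier":
            return self.levels[i, :, m.loc(tier, "cohort")]
        cls = m.tier_classes(tier)
        return self.levels[i][:, cls].mean(axis=1)


def accumulate_gain(
    gains: GainSchedule,
    matrices: GeneFlowMatrices,
    system: CrossSystemSpec | None = None,
) -> GainAccumulation:
    """Propagate per-season pathway gains through the system.

    Cumulative pathways inject their differential every season and every
    injection persists in descendants; non-cumulative pathways
    (multiplier/crossbred-origin parents) contribute only while the
    selected parents remain in service -- their differential is re-zeroed
    after one turnover of the receiving tier.
    """
    ids = [g.id for g in matrices.groups]
    if gains.pathway_ids != ids:
        raise ValueError("gain schedule pathways do not match the system")
    n_traits, k, _ = gains.sd.shape
    l = gains.n_seasons
    n = matrices.n
    inj = {g.id: matrices.injection(g.id) for g in matrices.groups}
    cum = {g.id: g.cumulative for g in matrices.groups}
    window = {}
    for g in matrices.groups:
        t = matrices.tiers[g.tier]
        window[g.id] = max(
            matrices.system.lifetime(g.tier, 1) if t.kind != "terminal" else 1, 1
        )

    levels = np.zeros((n_traits, l + 1, n))
    # single-event propagation vectors per pathway, reused across seasons
    prop: dict[str, list[np.ndarray]] = {j: [inj[j]] for j in ids}
    for tau in range(1, l + 1):
        for j in ids:
            prop[j].append(matrices.T @ prop[j][-1])

    for i in range(n_traits):
        for t in range(1, l + 1):
            lev = np.zeros(n)
            for jdx, j in enumerate(ids):
                zs = range(1, t + 1)
                for z in zs:
                    sd = gains.sd[i, jdx, z]
                    if sd == 0.0:
                        continue
                    if not cum[j] and (t - z) >= window[j]:
                        continue
                    lev += sd * prop[j][t - z]
            levels[i, t] = lev

    g: dict[tuple[str, str], float] = {}
    for i, tr in enumerate(gains.traits):
        for tier in matrices.tiers:
            h = matrices.realization_vector(tier)
            g[(tr, tier)] = float(sum(h @ levels[i, t] for t in range(l + 1)))
    return GainAccumulation(levels=levels, g=g, traits=gains.traits,
                            matrices=matrices)


# ---------------------------------------------------------------------------
# phenotype prediction
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTrajectory:
    """Predicted per-tier, per-season phenotype means for one trait."""

    trait: str
    means: pd.DataFrame        # index: season, columns: tier
    initial: dict[str, float]

    def tier(self, name: str) -> np.ndarray:
        return self.means[name].to_numpy()


def initial_tier_means(
    system: CrossSystemSpec, breed_means: dict[str, float]
) -> dict[str, float]:
    """Season-0 tier means under the additive cross-mean rule: a crossbred
    tier starts at the average of its parental tier means, applied
    recursively down the pyramid (no heterosis)."""
    tiers = build_tiers(system)
    out: dict[str, float] = {}
    for t in tiers.values():
        if t.kind in ("nucleus", "multiplier"):
            if t.breed not in breed_means:
                raise KeyError(f"no initial mean for breed {t.breed!r}")
            out[t.name] = float(breed_means[t.breed])
        else:
            out[t.name] = 0.5 * (out[t.sire_source] + out[t.dam_source])
    return out


def predict_phenotype(
    system: CrossSystemSpec,
    initial_means: dict[str, float],
    acc: GainAccumulation,
    trait: str | None = None,
) -> PhenotypeTrajectory:
    """Tier means over seasons: initial cross-mean plus accumulated gain."""
    trait = trait or acc.traits[0]
    init = initial_tier_means(system, initial_means)
    l = acc.levels.shape[1] - 1
    cols = {}
    for tier in acc.matrices.tiers:
        cols[tier] = init[tier] + acc.tier_level(trait, tier)
    df = pd.DataFrame(cols, index=pd.RangeIndex(l + 1, name="season"))
    return PhenotypeTrajectory(trait=trait, means=df, initial=init)
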