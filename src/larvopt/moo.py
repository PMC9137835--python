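"""Multi-objective optimization of rearing conditions over the finite design.

The 23 surrogate-predicted responses are optimized simultaneously — all
maximized except crude ash and the n6/n3 ratio, which are minimized.  The
decision space is the 18 categorical conditions, so the exact Pareto front is
obtainable by exhaustive enumeration; an NSGA-II-style genetic algorithm
(nondominated sorting + crowding-distance selection on 3-gene integer
chromosomes) is provided as well, and on this finite space is expected to
return exactly the enumerated front.

Because most of a 23-objective candidate set is mutually nondominated, a
single recommended condition is chosen from the front as the member closest
(Euclidean, after ideal/nadir normalization over the front) to the ideal
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import (
    HARVEST_LEVELS,
    MINIMIZE,
    RESPONSE_CATALOG,
    RESPONSE_NAMES,
    SPECIES_LEVELS,
    SUBSTRATE_LEVELS,
    DesignPoint,
    design_space,
)
from .surrogate import MLPSurrogate

_GENE_SIZES = (len(SPECIES_LEVELS), len(SUBSTRATE_LEVELS), len(HARVEST_LEVELS))


def _level_order(point: DesignPoint) -> tuple[int, int, int]:
    """Documented level order: TM, ZM | carrot, cabbage, mixture | 90, 97, 104."""
    return (
        SPECIES_LEVELS.index(point.species),
        SUBSTRATE_LEVELS.index(point.substrate),
        HARVEST_LEVELS.index(point.harvest_days),
    )


@dataclass(frozen=True)
class ObjectiveSpec:
    """Objective names and senses (+1 maximize, -1 minimize), catalog order."""

    names: tuple[str, ...] = RESPONSE_NAMES
    senses: tuple[int, ...] = tuple(
        -1 if e.direction_in_moo == MINIMIZE else 1 for e in RESPONSE_CATALOG
    )

    def __post_init__(self) -> None:
        if len(self.names) != len(self.senses):
            raise ValueError("names and senses must have equal length")
        if not set(self.senses) <= {-1, 1}:
            raise ValueError("senses must be +1 (maximize) or -1 (minimize)")


DEFAULT_OBJECTIVES = ObjectiveSpec()


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings, sized for the 18-point space."""

    population: int = 20
    generations: int = 50
    crossover_rate: float = 0.9
    mutation_rate: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must be in [0, 1]")


@dataclass
class ParetoFront:
    """Nondominated rearing conditions with their predicted objective vectors."""

    members: list[tuple[DesignPoint, pd.Series]]
    recommended: DesignPoint
    provenance: str
    ga_stats: dict = field(default_factory=dict)

    @property
    def member_points(self) -> set[DesignPoint]:
        return {p for p, _ in self.members}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for point, values in self.members:
            row = {
                "species": point.species,
                "substrate": point.substrate,
                "harvest_days": point.harvest_days,
                **{k: float(values[k]) for k in values.index},
                "recommended": point == self.recommended,
                "provenance": self.provenance,
            }
            rows.append(row)
        return pd.DataFrame(rows)


def dominates(a, b, spec: ObjectiveSpec = DEFAULT_OBJECTIVES) -> bool:
    """True iff ``a`` is at least as good as ``b`` in every objective (per its
    direction) and strictly better in at least one."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape != (len(spec.senses),):
        raise ValueError(
            f"objective vectors must have length {len(spec.senses)}, "
            f"got {a.shape} and {b.shape}"
        )
    s = np.asarray(spec.senses, dtype=float)
    ga, gb = s * a, s * b
    return bool(np.all(ga >= gb) and np.any(ga > gb))


def predict_objectives(
    models: Sequence[MLPSurrogate],
    points: Sequence[DesignPoint] | None = None,
    spec: ObjectiveSpec = DEFAULT_OBJECTIVES,
) -> pd.DataFrame:
    """Stack the group surrogates' predictions into one (points x objectives)
    table in catalog column order."""
    pts = list(points) if points is not None else list(design_space())
    frames = [m.predict(pts) for m in models]
    table = pd.concat(frames, axis=1)
    missing = [n for n in spec.names if n not in table.columns]
    if missing:
        raise ValueError(f"surrogates do not cover objectives: {missing}")
    table = table[list(spec.names)]
    table.index = pd.RangeIndex(len(pts))
    table.insert(0, "_point", pts)
    return table


def _nondominated_indices(values: np.ndarray, senses: np.ndarray) -> list[int]:
    g = values * senses
    keep = []
    for i in range(len(g)):
        dominated = False
        for j in range(len(g)):
            if i != j and np.all(g[j] >= g[i]) and np.any(g[j] > g[i]):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep


def enumerate_front(
    models: Sequence[MLPSurrogate], spec: ObjectiveSpec = DEFAULT_OBJECTIVES
) -> ParetoFront:
    """Exact Pareto front by pairwise dominance over all 18 conditions."""
    table = predict_objectives(models, None, spec)
    pts = list(table["_point"])
    values = table[list(spec.names)].to_numpy(dtype=float)
    keep = _nondominated_indices(values, np.asarray(spec.senses, dtype=float))
    members = [(pts[i], pd.Series(values[i], index=list(spec.names))) for i in keep]
    recommended = select_recommended_members(members, spec)
    return ParetoFront(members=members, recommended=recommended, provenance="enumeration")


# ---------------------------------------------------------------------------
# NSGA-II-style GA on integer chromosomes


def _chromosome_to_point(genes: tuple[int, int, int]) -> DesignPoint:
    return DesignPoint(
        SPECIES_LEVELS[genes[0]], SUBSTRATE_LEVELS[genes[1]], HARVEST_LEVELS[genes[2]]
    )


def _fast_nondominated_sort(g: np.ndarray) -> list[list[int]]:
    n = len(g)
    dominated_by = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if np.all(g[i] >= g[j]) and np.any(g[i] > g[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif np.all(g[j] >= g[i]) and np.any(g[j] > g[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = []
    current = [i for i in range(n) if dom_count[i] == 0]
    while current:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def _crowding_distance(g: np.ndarray) -> np.ndarray:
    n, m = g.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(g[:, k], kind="stable")
        span = g[order[-1], k] - g[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span == 0:
            continue
        for r in range(1, n - 1):
            dist[order[r]] += (g[order[r + 1], k] - g[order[r - 1], k]) / span
    return dist


def ga_front(
    models: Sequence[MLPSurrogate],
    spec: ObjectiveSpec = DEFAULT_OBJECTIVES,
    ga_config: GAConfig = GAConfig(),
) -> ParetoFront:
    """NSGA-II-style genetic search over the categorical design space.

    Maintains an external archive of every nondominated chromosome seen;
    returns the archive's nondominated set after the final generation.
    Seeded and reproducible.
    """
    rng = np.random.default_rng(ga_config.seed)
    senses = np.asarray(spec.senses, dtype=float)
    cache: dict[tuple[int, int, int], np.ndarray] = {}

    def evaluate(genes: tuple[int, int, int]) -> np.ndarray:
        if genes not in cache:
            point = _chromosome_to_point(genes)
            table = predict_objectives(models, [point], spec)
            cache[genes] = table[list(spec.names)].to_numpy(dtype=float)[0]
        return cache[genes]

    def random_genes() -> tuple[int, int, int]:
        return tuple(int(rng.integers(0, s)) for s in _GENE_SIZES)

    pop = [random_genes() for _ in range(ga_config.population)]
    values = np.array([evaluate(c) for c in pop])

    def tournament(rank: np.ndarray, crowd: np.ndarray) -> int:
        i, j = rng.integers(0, len(pop), size=2)
        if rank[i] != rank[j]:
            return int(i if rank[i] < rank[j] else j)
        return int(i if crowd[i] >= crowd[j] else j)

    for _ in range(ga_config.generations):
        g = values * senses
        fronts = _fast_nondominated_sort(g)
        rank = np.empty(len(pop), dtype=int)
        crowd = np.empty(len(pop))
        for r, fr in enumerate(fronts):
            rank[fr] = r
            crowd[fr] = _crowding_distance(g[fr])

        offspring = []
        while len(offspring) < ga_config.population:
            p1 = pop[tournament(rank, crowd)]
            p2 = pop[tournament(rank, crowd)]
            if rng.random() < ga_config.crossover_rate:
                child = tuple(
                    p1[k] if rng.random() < 0.5 else p2[k] for k in range(3)
                )
            else:
                child = p1
            child = tuple(
                int(rng.integers(0, _GENE_SIZES[k]))
                if rng.random() < ga_config.mutation_rate
                else child[k]
                for k in range(3)
            )
            offspring.append(child)
        off_values = np.array([evaluate(c) for c in offspring])

        union = pop + offspring
        union_values = np.vstack([values, off_values])
        g = union_values * senses
        fronts = _fast_nondominated_sort(g)
        new_idx: list[int] = []
        for fr in fronts:
            if len(new_idx) + len(fr) <= ga_config.population:
                new_idx.extend(fr)
            else:
                crowd = _crowding_distance(g[fr])
                order = sorted(fr, key=lambda i: -crowd[fr.index(i)])
                new_idx.extend(order[: ga_config.population - len(new_idx)])
                break
        pop = [union[i] for i in new_idx]
        values = union_values[new_idx]

    # archive = everything evaluated; report its nondominated subset
    genes_seen = list(cache.keys())
    arch_values = np.array([cache[c] for c in genes_seen])
    keep = _nondominated_indices(arch_values, senses)
    members = [
        (_chromosome_to_point(genes_seen[i]), pd.Series(arch_values[i], index=list(spec.names)))
        for i in keep
    ]
    members.sort(key=lambda m: _level_order(m[0]))
    recommended = select_recommended_members(members, spec)
    return ParetoFront(
        members=members,
        recommended=recommended,
        provenance="ga",
        ga_stats={
            "generations": ga_config.generations,
            "population": ga_config.population,
            "seed": ga_config.seed,
            "evaluations": len(cache),
        },
    )


def select_recommended_members(
    members: list[tuple[DesignPoint, pd.Series]],
    spec: ObjectiveSpec = DEFAULT_OBJECTIVES,
) -> DesignPoint:
    """Distance-to-ideal selection over front members.

    Each objective is normalized to [0, 1] with the ideal/nadir over the
    members (degenerate objectives contribute 0); the member with the
    smallest Euclidean distance to the ideal point wins.  Ties break by (a)
    the larger number of objectives at which the member is best, then (b)
    documented level order.
    """
    if not members:
        raise ValueError("empty Pareto front")
    values = np.array([m[1].to_numpy(dtype=float) for m in members])
    senses = np.asarray(spec.senses, dtype=float)
    g = values * senses
    ideal = g.max(axis=0)
    nadir = g.min(axis=0)
    span = ideal - nadir
    with np.errstate(invalid="ignore", divide="ignore"):
        deficit = (ideal - g) / span  # 0 = ideal, 1 = nadir
    deficit = np.where(span == 0, 0.0, deficit)
    dist = np.sqrt((deficit**2).sum(axis=1))
    n_best = (g == ideal).sum(axis=1)
    order = sorted(
        range(len(members)),
        key=lambda i: (dist[i], -n_best[i], _level_order(members[i][0])),
    )
    return members[order[0]][0]


def select_recommended(front: ParetoFront, spec: ObjectiveSpec = DEFAULT_OBJECTIVES) -> DesignPoint:
    return select_recommended_members(front.members, spec)
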