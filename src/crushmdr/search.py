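"""The Crush multiobjective evolutionary search engine.

Crush evolves candidate SNP-set models under three jointly optimized
objectives — maximize the QMDR t-statistic, maximize the mean pairwise
interaction information of the SNPs in the model, minimize the model order —
ranked by NSGA-II nondominated sorting with crowding-distance diversity.

Two breeding regimes cooperate, mirroring a client/worker layout:

* a central *steady-state* population on the client breeds seed models
  (two rank/crowding tournaments of size 3, the second winner mutated at a
  dataset-size-dependent per-SNP rate, then any-point crossover) which seed
  *generational evolutionary tasks*;
* each task runs generational evolution (crossover 90% of the time from a
  parsimony tournament of size 6 paired with a rank/crowding tournament of
  size 3, mutation-only the remaining 10%) and returns its subpopulation for
  merging back into the steady-state population with elitist NSGA-II
  truncation.

The original deployment scattered tasks across opportunistic cloud nodes;
here tasks run as an in-process island loop with the identical algorithmic
contract and deterministic per-task random streams, so results depend only
on the root seed.  Initial models are *sensibly initialized*: sizes uniform
in [1, 5] by default, and each SNP after the first is drawn from the
expert-knowledge lookup table (its predecessor's best partner) half the
time.

A matched-budget random search over the same model distribution (expert
knowledge disabled) serves as the baseline.  Every unique SNP set is scored
once; a score cache makes re-evaluations free, and only cache misses consume
the evaluation budget.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

try:
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

from .data import GenotypeDataset
from .entropy import ExpertKnowledgeTable, build_expert_knowledge
from .qmdr import DEFAULT_MAX_K, DatasetStats, ModelScore, fast_t

__all__ = [
    "CandidateModel",
    "SearchConfig",
    "SearchResult",
    "BudgetExhausted",
    "Evaluator",
    "sample_initial_model",
    "nondominated_sort",
    "crowding_distance",
    "tournament_rank_crowding",
    "tournament_parsimony",
    "any_point_crossover",
    "mutate",
    "run_evolutionary_task",
    "run_crush",
    "run_random_search",
]


@dataclass
class CandidateModel:
    """A candidate solution: an ordered set of distinct SNP indices."""

    snps: tuple
    score: ModelScore | None = None
    pareto_rank: int | None = None
    crowding: float | None = None

    def __post_init__(self) -> None:
        if type(self.snps) is not tuple:
            self.snps = tuple(int(i) for i in self.snps)
        if len(self.snps) == 0:
            raise ValueError("model must contain at least one SNP")
        if len(set(self.snps)) != len(self.snps):
            raise ValueError(f"duplicate SNP indices in {self.snps}")

    @property
    def key(self) -> tuple:
        return tuple(sorted(self.snps))


@dataclass
class SearchConfig:
    """Tunable parameters of the Crush search.

    Defaults follow Crush's stated parameterization (initial
    model sizes 3 +/- 2, expert-knowledge seeding probability 0.5, task
    crossover probability 0.9, tournament sizes 3 and 6, per-SNP mutation
    rate 5% for ~100-SNP and 0.5% for >=1000-SNP datasets); population
    sizes and the evaluation budget are desk-scale choices exposed here.
    """

    init_size_center: int = 3
    init_size_delta: int = 2
    ek_seed_prob: float = 0.5
    steady_state_pop: int = 200
    task_pop: int = 50
    task_generations: int = 25
    n_tasks_per_round: int = 4
    crossover_prob_task: float = 0.9
    per_snp_mutation_rate: float | None = None  # None -> by dataset size
    tournament_size_rank: int = 3
    tournament_size_parsimony: int = 6
    evaluation_budget: int = 50_000
    max_model_size: int = DEFAULT_MAX_K
    welch: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("ek_seed_prob", "crossover_prob_task"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0,1]")
        if self.per_snp_mutation_rate is not None and not (
            0.0 <= self.per_snp_mutation_rate <= 1.0
        ):
            raise ValueError("per_snp_mutation_rate must be in [0,1]")
        for name in (
            "init_size_center",
            "steady_state_pop",
            "task_pop",
            "task_generations",
            "n_tasks_per_round",
            "tournament_size_rank",
            "tournament_size_parsimony",
            "evaluation_budget",
            "max_model_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.init_size_delta < 0:
            raise ValueError("init_size_delta must be >= 0")

    def resolve_mutation_rate(self, n_snps: int) -> float:
        """Per-SNP mutation rate: 0.5% for >=1000-SNP datasets, 5% below."""
        if self.per_snp_mutation_rate is not None:
            return self.per_snp_mutation_rate
        return 0.005 if n_snps >= 1000 else 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "SearchConfig":
        """Load a config from YAML or ``key=value`` lines."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if isinstance(data, str) or data is None:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                data[k.strip()] = yaml.safe_load(v.strip())
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class SearchResult:
    """Outcome of one search run."""

    pareto_front: list
    archive_size: int  # total fitness evaluations consumed
    history: list
    seed: int
    snp_ids: list[str] | None = None
    population_front_size: int = 0
    archive_front_size: int = 0

    def front_snp_indices(self) -> set:
        return set(itertools.chain.from_iterable(m.snps for m in self.pareto_front))

    def front_snp_ids(self) -> set:
        if self.snp_ids is None:
            raise ValueError("result carries no SNP identifiers")
        return {self.snp_ids[i] for i in self.front_snp_indices()}


class BudgetExhausted(RuntimeError):
    """Raised by the evaluator when the evaluation budget is spent."""


def _objectives(models) -> np.ndarray:
    """(t, mean interaction info, -size): all maximized."""
    n = len(models)
    out = np.empty((n, 3))
    for i, m in enumerate(models):
        if m.score is None:
            raise ValueError("model must be scored before ranking")
        out[i, 0] = m.score.t_statistic
        out[i, 1] = m.score.mean_interaction_info
        out[i, 2] = -m.score.size
    return out


def _rank_crowd_py(obj):
    """Ranks and crowding distances for a whole population in one pass."""
    n = obj.shape[0]
    dom = np.zeros((n, n), dtype=np.bool_)
    n_dominators = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ge = (
                obj[i, 0] >= obj[j, 0]
                and obj[i, 1] >= obj[j, 1]
                and obj[i, 2] >= obj[j, 2]
            )
            gt = (
                obj[i, 0] > obj[j, 0]
                or obj[i, 1] > obj[j, 1]
                or obj[i, 2] > obj[j, 2]
            )
            if ge and gt:
                dom[i, j] = True
                n_dominators[j] += 1
    ranks = np.full(n, -1, dtype=np.int64)
    rank = 0
    remaining = n
    while remaining > 0:
        current = np.flatnonzero(n_dominators == 0)
        for c in current:
            ranks[c] = rank
            n_dominators[c] = -1
        remaining -= len(current)
        for c in current:
            for j in range(n):
                if dom[c, j] and n_dominators[j] > 0:
                    n_dominators[j] -= 1
        rank += 1
    crowd = np.zeros(n)
    for r in range(rank):
        members = np.flatnonzero(ranks == r)
        m = len(members)
        if m == 0:
            continue
        for k in range(3):
            vals = obj[members, k]
            order = np.argsort(vals, kind="mergesort")
            lo = vals[order[0]]
            hi = vals[order[-1]]
            crowd[members[order[0]]] = np.inf
            crowd[members[order[-1]]] = np.inf
            span = hi - lo
            if span > 0:
                for p in range(1, m - 1):
                    idx = members[order[p]]
                    if not np.isinf(crowd[idx]):
                        crowd[idx] += (
                            vals[order[p + 1]] - vals[order[p - 1]]
                        ) / span
    return ranks, crowd


_rank_crowd_nb = (
    _numba.njit(_rank_crowd_py, cache=False) if _numba is not None else None
)


def _rank_from_objectives(obj: np.ndarray) -> np.ndarray:
    t, g, s = obj[:, 0], obj[:, 1], obj[:, 2]
    tc, gc, sc = t[:, None], g[:, None], s[:, None]
    # dom[i, j]: i dominates j
    dom = (
        (tc >= t) & (gc >= g) & (sc >= s) & ((tc > t) | (gc > g) | (sc > s))
    )
    n = len(obj)
    n_dominators = dom.sum(axis=0)
    ranks = np.full(n, -1, dtype=np.int64)
    current = np.flatnonzero(n_dominators == 0)
    rank = 0
    remaining = n
    while remaining:
        ranks[current] = rank
        remaining -= len(current)
        if remaining == 0:
            break
        n_dominators = n_dominators - dom[current].sum(axis=0)
        n_dominators[ranks >= 0] = -1
        current = np.flatnonzero(n_dominators == 0)
        rank += 1
    return ranks


def nondominated_sort(models) -> np.ndarray:
    """NSGA-II fast nondominated sorting.

    Model a dominates b iff a is >= b on both maximized objectives, <= on
    size, and strictly better on at least one.  Ranks (0 = Pareto front)
    are written onto the models and returned.
    """
    ranks = _rank_from_objectives(_objectives(models))
    for m, r in zip(models, ranks):
        m.pareto_rank = int(r)
    return ranks


def _crowding_from_objectives(obj: np.ndarray) -> np.ndarray:
    n = len(obj)
    dist = np.zeros(n)
    for k in range(obj.shape[1]):
        order = np.argsort(obj[:, k], kind="stable")
        vals = obj[order, k]
        rng_ = vals[-1] - vals[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if rng_ > 0:
            dist[order[1:-1]] += (vals[2:] - vals[:-2]) / rng_
    return dist


def crowding_distance(front) -> np.ndarray:
    """NSGA-II crowding distance for models sharing one rank.

    Boundary models per objective get +inf; interior models accumulate the
    range-normalized neighbor gap over the three objectives.
    """
    if len(front) == 0:
        raise ValueError("empty front")
    dist = _crowding_from_objectives(_objectives(front))
    for m, d in zip(front, dist):
        m.crowding = float(d)
    return dist


def assign_rank_and_crowding(models) -> tuple[np.ndarray, np.ndarray]:
    """Rank the population and compute crowding within each front."""
    obj = _objectives(models)
    if _rank_crowd_nb is not None:
        ranks, crowd = _rank_crowd_nb(obj)
    else:
        ranks = _rank_from_objectives(obj)
        crowd = np.zeros(len(models))
        for r in np.unique(ranks):
            members = np.flatnonzero(ranks == r)
            crowd[members] = _crowding_from_objectives(obj[members])
    for m, r, c in zip(models, ranks, crowd):
        m.pareto_rank = int(r)
        m.crowding = float(c)
    return ranks, crowd


def _rng_tiebreak(rng: np.random.Generator, candidates: list):
    if len(candidates) == 1:
        return candidates[0]
    return candidates[rng.integers(len(candidates))]


def tournament_rank_crowding(pop, size: int, rng: np.random.Generator):
    """Tournament: lowest Pareto rank, ties by highest crowding, then random."""
    if not pop:
        raise ValueError("empty population")
    entrants = [pop[i] for i in rng.integers(0, len(pop), size)]
    best_rank = min(m.pareto_rank for m in entrants)
    pool = [m for m in entrants if m.pareto_rank == best_rank]
    best_crowd = max(m.crowding for m in pool)
    pool = [m for m in pool if m.crowding == best_crowd]
    return _rng_tiebreak(rng, pool)


def tournament_parsimony(pop, size: int, rng: np.random.Generator):
    """Tournament favoring the smallest model order; ties broken at random."""
    if not pop:
        raise ValueError("empty population")
    entrants = [pop[i] for i in rng.integers(0, len(pop), size)]
    best = min(len(m.snps) for m in entrants)
    pool = [m for m in entrants if len(m.snps) == best]
    return _rng_tiebreak(rng, pool)


def _dedup_truncate(snps: list, max_size: int) -> tuple:
    seen = []
    for s in snps:
        if s not in seen:
            seen.append(s)
        if len(seen) == max_size:
            break
    return tuple(seen)


def any_point_crossover(
    parent_a: CandidateModel,
    parent_b: CandidateModel,
    rng: np.random.Generator,
    max_model_size: int = DEFAULT_MAX_K,
):
    """Any-point crossover: independent cut points, tails swapped.

    Duplicate SNPs within a child are removed keeping the first occurrence;
    an empty child is repaired to a single random SNP from either parent.
    Children may grow beyond either parent's size but are truncated at
    ``max_model_size``.
    """
    a, b = list(parent_a.snps), list(parent_b.snps)
    cut_a = int(rng.integers(0, len(a) + 1))
    cut_b = int(rng.integers(0, len(b) + 1))
    raw_a = a[:cut_a] + b[cut_b:]
    raw_b = b[:cut_b] + a[cut_a:]
    children = []
    for raw in (raw_a, raw_b):
        snps = _dedup_truncate(raw, max_model_size)
        if not snps:
            both = a + b
            snps = (both[rng.integers(len(both))],)
        children.append(CandidateModel(snps=snps))
    return children[0], children[1]


def mutate(
    model: CandidateModel,
    n_snps: int,
    per_snp_rate: float,
    rng: np.random.Generator,
) -> CandidateModel:
    """Point mutation: each position independently replaced with probability
    ``per_snp_rate`` by a uniformly drawn SNP not already in the model."""
    snps = list(model.snps)
    hits = rng.random(len(snps)) < per_snp_rate
    for pos in np.flatnonzero(hits):
        current = set(snps)
        if len(current) >= n_snps:
            continue  # no alternative SNP exists
        while True:
            candidate = int(rng.integers(n_snps))
            if candidate not in current:
                snps[pos] = candidate
                break
    return CandidateModel(snps=tuple(snps))


def sample_initial_model(
    ek: ExpertKnowledgeTable,
    n_snps: int,
    config: SearchConfig,
    rng: np.random.Generator,
) -> CandidateModel:
    """Sensible initialization of one model.

    Size uniform in [center-delta, center+delta] (clipped to [1, n_snps]);
    first SNP uniform; each further SNP is, with probability
    ``ek_seed_prob``, the best partner of the previously selected SNP
    (falling back to uniform when that partner is already in the model).
    """
    if n_snps < 2:
        raise ValueError("need at least two SNPs")
    lo = max(1, config.init_size_center - config.init_size_delta)
    hi = min(
        config.init_size_center + config.init_size_delta,
        n_snps,
        config.max_model_size,
    )
    size = int(rng.integers(lo, hi + 1))
    snps = [int(rng.integers(n_snps))]
    while len(snps) < size:
        prev = snps[-1]
        chosen = None
        if rng.random() < config.ek_seed_prob:
            partner = int(ek.best_partner[prev])
            if partner not in snps:
                chosen = partner
        if chosen is None:
            if n_snps > 2 * len(snps):
                while True:  # rejection sampling: few occupied indices
                    cand = int(rng.integers(n_snps))
                    if cand not in snps:
                        chosen = cand
                        break
            else:
                unused = np.setdiff1d(np.arange(n_snps), np.asarray(snps))
                chosen = int(unused[rng.integers(len(unused))])
        snps.append(chosen)
    return CandidateModel(snps=tuple(snps))


class Evaluator:
    """Scores models against a dataset with caching, budget accounting and a
    running nondominated archive.

    Re-evaluating an identical SNP set returns the cached score and consumes
    no budget; ``evaluations`` counts cache misses only.
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        ek: ExpertKnowledgeTable,
        budget: int,
        max_model_size: int = DEFAULT_MAX_K,
        welch: bool = False,
    ):
        self.stats = DatasetStats(dataset)
        self.ek = ek
        self.budget = int(budget)
        self.max_model_size = max_model_size
        self.welch = welch
        self.cache: dict = {}
        self.evaluations = 0
        self._arch_keys: list = []
        self._arch_obj = np.empty((0, 3))

    def exhausted(self) -> bool:
        return self.evaluations >= self.budget

    def _mean_gain(self, key: tuple) -> float:
        k = len(key)
        if k == 1:
            return 0.0
        gain = self.ek.gain
        total = 0.0
        for a, b in itertools.combinations(key, 2):
            total += gain[a, b]
        return 2.0 * total / (k * (k - 1))

    def score(self, snps) -> ModelScore:
        key = tuple(sorted(snps))
        if len(set(key)) != len(key):
            raise ValueError(f"duplicate SNP indices in {snps}")
        if len(key) > self.max_model_size:
            raise ValueError(f"model order {len(key)} exceeds {self.max_model_size}")
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        if self.exhausted():
            raise BudgetExhausted
        t, valid = fast_t(self.stats, key, welch=self.welch)
        score = ModelScore(
            t_statistic=t if valid else 0.0,
            mean_interaction_info=self._mean_gain(key),
            size=len(key),
            valid=valid,
        )
        self.cache[key] = score
        self.evaluations += 1
        self._archive_insert(key, score)
        return score

    def _archive_insert(self, key: tuple, score: ModelScore) -> None:
        obj = np.array(
            [score.t_statistic, score.mean_interaction_info, -score.size]
        )
        arr = self._arch_obj
        if len(arr):
            ge = (arr >= obj).all(axis=1)
            gt = (arr > obj).any(axis=1)
            if np.any(ge & gt):
                return  # dominated by an archived model
            le = (arr <= obj).all(axis=1)
            lt = (arr < obj).any(axis=1)
            keep = ~(le & lt)
            if not keep.all():
                self._arch_keys = [
                    k for k, kp in zip(self._arch_keys, keep) if kp
                ]
                arr = arr[keep]
        self._arch_keys.append(key)
        self._arch_obj = np.vstack([arr, obj[None, :]])

    def archive_models(self) -> list:
        return [
            CandidateModel(snps=key, score=self.cache[key])
            for key in self._arch_keys
        ]


def elitist_select(models, size: int) -> list:
    """Environmental selection: rank, then crowding, deterministic ties."""
    ranks, crowd = assign_rank_and_crowding(models)
    order = np.lexsort((np.arange(len(models)), -crowd, ranks))
    return [models[i] for i in order[:size]]


def run_evolutionary_task(
    seed_pop,
    evaluator: Evaluator,
    config: SearchConfig,
    rng: np.random.Generator,
):
    """One generational evolutionary task (an island/worker).

    Each generation breeds ``task_pop`` children — crossover of a parsimony
    tournament (size 6) winner with a rank/crowding tournament (size 3)
    winner 90% of the time, otherwise mutation of a uniformly drawn model —
    then re-ranks and truncates elitist-style back to ``task_pop``.

    Returns ``(subpopulation, partial)``; ``partial`` is True when the
    evaluation budget ran out mid-task.
    """
    if any(m.score is None for m in seed_pop):
        raise ValueError("seed population must be scored")
    n_snps = evaluator.stats.genotypes.shape[1]
    rate = config.resolve_mutation_rate(n_snps)
    pop = list(seed_pop)
    partial = False
    assign_rank_and_crowding(pop)
    max_size = config.max_model_size
    for _gen in range(config.task_generations):
        n_pop = len(pop)
        n_events = config.task_pop  # each breeding event yields >= 1 child
        # batch all random draws and tournament winners for the generation
        branch = rng.random(n_events)
        p1_win = _batch_tournament_parsimony(
            pop, n_events, config.tournament_size_parsimony, rng
        )
        p2_win = _batch_tournament_rank_crowding(
            pop, n_events, config.tournament_size_rank, rng
        )
        mut_pick = rng.integers(0, n_pop, n_events)
        cuts = rng.random((n_events, 2))
        children = []
        for e in range(n_events):
            if len(children) >= config.task_pop:
                break
            if branch[e] < config.crossover_prob_task:
                a = pop[p1_win[e]].snps
                b = pop[p2_win[e]].snps
                ca = int(cuts[e, 0] * (len(a) + 1))
                cb = int(cuts[e, 1] * (len(b) + 1))
                for raw in (a[:ca] + b[cb:], b[:cb] + a[ca:]):
                    if 0 < len(raw) <= max_size and len(set(raw)) == len(raw):
                        snps = raw
                    else:
                        snps = _dedup_truncate(raw, max_size)
                        if not snps:
                            both = a + b
                            snps = (both[rng.integers(len(both))],)
                    children.append(CandidateModel(snps=snps))
            else:
                children.append(mutate(pop[mut_pick[e]], n_snps, rate, rng))
        children = children[: config.task_pop]
        scored = []
        for child in children:
            try:
                child.score = evaluator.score(child.snps)
            except BudgetExhausted:
                partial = True
                break
            scored.append(child)
        pop = elitist_select(pop + scored, config.task_pop)
        if partial:
            break
    return pop, partial


def _batch_tournament_parsimony(pop, n_events, size, rng) -> np.ndarray:
    """Winners of ``n_events`` parsimony tournaments, ties uniform."""
    sizes = np.fromiter((len(m.snps) for m in pop), float, len(pop))
    idx = rng.integers(0, len(pop), (n_events, size))
    entrants = sizes[idx]
    best = entrants.min(axis=1, keepdims=True)
    tie_key = np.where(entrants == best, rng.random(idx.shape), -1.0)
    return idx[np.arange(n_events), tie_key.argmax(axis=1)]


def _batch_tournament_rank_crowding(pop, n_events, size, rng) -> np.ndarray:
    """Winners of ``n_events`` rank/crowding tournaments, ties uniform."""
    n_pop = len(pop)
    ranks = np.fromiter((m.pareto_rank for m in pop), float, n_pop)
    crowds = np.fromiter((m.crowding for m in pop), float, n_pop)
    idx = rng.integers(0, n_pop, (n_events, size))
    r = ranks[idx]
    best_rank = r.min(axis=1, keepdims=True)
    c = np.where(r == best_rank, crowds[idx], -np.inf)
    best_crowd = c.max(axis=1, keepdims=True)
    winners = (r == best_rank) & (c == best_crowd)
    tie_key = np.where(winners, rng.random(idx.shape), -1.0)
    return idx[np.arange(n_events), tie_key.argmax(axis=1)]


def _front_of(models) -> list:
    """Rank-0 subset of a model list, deduplicated by SNP set."""
    seen = set()
    unique = []
    for m in models:
        if m.key not in seen:
            seen.add(m.key)
            unique.append(m)
    if not unique:
        return []
    ranks = nondominated_sort(unique)
    front = [m for m, r in zip(unique, ranks) if r == 0]
    crowding_distance(front)
    return front


def run_crush(dataset: GenotypeDataset, config: SearchConfig) -> SearchResult:
    """Full Crush-MDR search on one dataset.

    Builds the expert-knowledge table, sensibly initializes the steady-state
    population, then alternates client-side breeding of task seeds with
    generational tasks until the evaluation budget is consumed.  Fully
    reproducible from ``config.seed``.
    """
    config.validate()
    if dataset.n_snps < 2:
        raise ValueError("dataset must contain at least two SNPs")
    if config.evaluation_budget < config.steady_state_pop:
        raise ValueError("evaluation budget smaller than the initial population")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    ek = build_expert_knowledge(dataset)
    evaluator = Evaluator(
        dataset,
        ek,
        config.evaluation_budget,
        config.max_model_size,
        config.welch,
    )
    n_snps = dataset.n_snps
    rate = config.resolve_mutation_rate(n_snps)

    pop = []
    while len(pop) < config.steady_state_pop and not evaluator.exhausted():
        model = sample_initial_model(ek, n_snps, config, rng)
        try:
            model.score = evaluator.score(model.snps)
        except BudgetExhausted:
            break
        pop.append(model)
    assign_rank_and_crowding(pop)

    history = []
    round_idx = 0
    while not evaluator.exhausted():
        round_idx += 1
        subpops = []
        for task_idx in range(config.n_tasks_per_round):
            seeds = []
            while len(seeds) < config.task_pop:
                p1 = tournament_rank_crowding(
                    pop, config.tournament_size_rank, rng
                )
                p2 = tournament_rank_crowding(
                    pop, config.tournament_size_rank, rng
                )
                p2 = mutate(p2, n_snps, rate, rng)
                c1, c2 = any_point_crossover(p1, p2, rng, config.max_model_size)
                seeds.extend([c1, c2])
            seeds = seeds[: config.task_pop]
            scored_seeds = []
            for seed_model in seeds:
                try:
                    seed_model.score = evaluator.score(seed_model.snps)
                except BudgetExhausted:
                    break
                scored_seeds.append(seed_model)
            if not scored_seeds:
                break
            task_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, round_idx, task_idx])
            )
            sub, _partial = run_evolutionary_task(
                scored_seeds, evaluator, config, task_rng
            )
            subpops.append(sub)
            if evaluator.exhausted():
                break
        merged = pop + [m for sub in subpops for m in sub]
        pop = elitist_select(merged, config.steady_state_pop)
        pop_front = [m for m in pop if m.pareto_rank == 0]
        best_t = max((m.score.t_statistic for m in pop), default=0.0)
        history.append(
            {
                "round": round_idx,
                "evaluations": evaluator.evaluations,
                "best_t": float(best_t),
                "front_size": len(pop_front),
            }
        )
        if not subpops:
            break

    population_front = _front_of(pop)
    archive = evaluator.archive_models()
    front = _front_of(pop + archive)
    return SearchResult(
        pareto_front=front,
        archive_size=evaluator.evaluations,
        history=history,
        seed=config.seed,
        snp_ids=list(dataset.snp_ids),
        population_front_size=len(population_front),
        archive_front_size=len(archive),
    )


def run_random_search(
    dataset: GenotypeDataset,
    ek: ExpertKnowledgeTable,
    budget: int,
    config: SearchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SearchResult:
    """Matched-budget random baseline.

    Draws models from the same initial-sampling distribution with expert
    knowledge disabled (pure uniform choices) and returns the Pareto front
    of everything evaluated.
    """
    config = config if config is not None else SearchConfig()
    rng = (
        rng
        if rng is not None
        else np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    )
    cfg = replace(config, ek_seed_prob=0.0)
    evaluator = Evaluator(dataset, ek, budget, cfg.max_model_size, cfg.welch)
    max_draws = 1000 + 50 * budget
    draws = 0
    while not evaluator.exhausted() and draws < max_draws:
        model = sample_initial_model(ek, dataset.n_snps, cfg, rng)
        draws += 1
        try:
            evaluator.score(model.snps)
        except BudgetExhausted:
            break
    front = _front_of(evaluator.archive_models())
    return SearchResult(
        pareto_front=front,
        archive_size=evaluator.evaluations,
        history=[],
        seed=cfg.seed,
        snp_ids=list(dataset.snp_ids),
        population_front_size=0,
        archive_front_size=len(front),
    )
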