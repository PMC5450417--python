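"""scikit-learn estimator wrappers around the search engines.

Both estimators are feature selectors: ``fit(X, y)`` runs the search on a
0/1/2-coded genotype matrix and a continuous trait, and ``transform``
selects the columns of the SNPs that appear in the final Pareto front.
They compose with sklearn pipelines and ``clone``/``get_params``.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_random_state

from .data import GenotypeDataset
from .entropy import build_expert_knowledge
from .search import SearchConfig, run_crush, run_random_search

__all__ = ["CrushMDR", "RandomSearchBaseline"]


def _resolve_seed(random_state) -> int:
    if random_state is None or isinstance(random_state, numbers.Integral):
        return int(random_state or 0)
    return int(check_random_state(random_state).randint(2**31))


class _BaseSearchSelector(SelectorMixin, BaseEstimator):
    def __init__(
        self,
        *,
        evaluation_budget=5000,
        init_size_center=3,
        init_size_delta=2,
        ek_seed_prob=0.5,
        steady_state_pop=200,
        task_pop=50,
        task_generations=25,
        n_tasks_per_round=4,
        crossover_prob_task=0.9,
        per_snp_mutation_rate=None,
        tournament_size_rank=3,
        tournament_size_parsimony=6,
        max_model_size=10,
        welch=False,
        random_state=None,
    ):
        self.evaluation_budget = evaluation_budget
        self.init_size_center = init_size_center
        self.init_size_delta = init_size_delta
        self.ek_seed_prob = ek_seed_prob
        self.steady_state_pop = steady_state_pop
        self.task_pop = task_pop
        self.task_generations = task_generations
        self.n_tasks_per_round = n_tasks_per_round
        self.crossover_prob_task = crossover_prob_task
        self.per_snp_mutation_rate = per_snp_mutation_rate
        self.tournament_size_rank = tournament_size_rank
        self.tournament_size_parsimony = tournament_size_parsimony
        self.max_model_size = max_model_size
        self.welch = welch
        self.random_state = random_state

    def _config(self) -> SearchConfig:
        cfg = SearchConfig(
            init_size_center=self.init_size_center,
            init_size_delta=self.init_size_delta,
            ek_seed_prob=self.ek_seed_prob,
            steady_state_pop=self.steady_state_pop,
            task_pop=self.task_pop,
            task_generations=self.task_generations,
            n_tasks_per_round=self.n_tasks_per_round,
            crossover_prob_task=self.crossover_prob_task,
            per_snp_mutation_rate=self.per_snp_mutation_rate,
            tournament_size_rank=self.tournament_size_rank,
            tournament_size_parsimony=self.tournament_size_parsimony,
            evaluation_budget=self.evaluation_budget,
            max_model_size=self.max_model_size,
            welch=self.welch,
            seed=_resolve_seed(self.random_state),
        )
        cfg.validate()
        return cfg

    def _dataset(self, X, y) -> GenotypeDataset:
        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        ids = [f"snp{j}" for j in range(X.shape[1])]
        return GenotypeDataset(
            genotypes=X, phenotype=y, snp_ids=ids,
            phenotype_kind="quantitative",
        )

    def _run(self, dataset):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y):
        """Run the search; the support mask is the union of front SNPs."""
        dataset = self._dataset(X, y)
        self.n_features_in_ = dataset.n_snps
        self.result_ = self._run(dataset)
        self.pareto_front_ = self.result_.pareto_front
        mask = np.zeros(dataset.n_snps, dtype=bool)
        mask[sorted(self.result_.front_snp_indices())] = True
        self.support_ = mask
        self.best_model_ = max(
            self.pareto_front_,
            key=lambda m: m.score.t_statistic,
            default=None,
        )
        self.archive_size_ = self.result_.archive_size
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class CrushMDR(_BaseSearchSelector):
    """Crush-MDR evolutionary SNP-subset selector.

    Examples
    --------
    >>> sel = CrushMDR(evaluation_budget=2000, random_state=0)
    >>> Xt = sel.fit(X, y).transform(X)   # doctest: +SKIP
    """

    def _run(self, dataset):
        return run_crush(dataset, self._config())


class RandomSearchBaseline(_BaseSearchSelector):
    """Matched-budget random-search selector (the null search engine)."""

    def _run(self, dataset):
        cfg = self._config()
        ek = build_expert_knowledge(dataset)
        return run_random_search(dataset, ek, cfg.evaluation_budget, cfg)
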