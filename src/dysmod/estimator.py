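"""Scikit-learn-style estimator front end to the evolutionary optimiser.

:class:`EvolutionaryModuleFinder` behaves like a clustering estimator: it is
configured in ``__init__`` (so ``get_params``/``set_params``/``clone`` work),
fitted on a :class:`~dysmod.network.ScoredNetwork`, and exposes its solution
through trailing-underscore attributes, including a per-node ``labels_``
array (0 = background, 1 = module 1, 2 = module 2).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .evolution import EAParameters, evolve
from .network import ScoredNetwork

__all__ = ["EvolutionaryModuleFinder"]


class EvolutionaryModuleFinder(BaseEstimator):
    """Find differentially expressed connected module(s) in a scored network.

    Parameters mirror :class:`~dysmod.evolution.EAParameters`; see there for
    semantics. ``random_state`` seeds the single RNG driving the run.

    Attributes (after ``fit``)
    --------------------------
    best_module_ : list[str]
        Sorted labels of the condition-1 module (the only module in overlap
        mode).
    best_module2_ : list[str]
        Sorted labels of the condition-2 module (== ``best_module_`` in
        overlap mode).
    best_fitness_ : FitnessValue
        Components of the winning fitness evaluation.
    history_ : list[float]
        Best F_bar per generation (non-increasing under elitism).
    labels_ : ndarray of shape (n_nodes,)
        Per-node membership: 0 background, 1 module 1, 2 module 2.
    result_ : RunResult
        The full run record.
    """

    def __init__(
        self,
        mode: str = "overlap",
        subnetwork_size: int = 10,
        subnetwork_size2: int | None = None,
        generations: int = 100,
        population_size: int = 200,
        crossover_rate: float = 0.1,
        mutation_rate: float = 0.9,
        mutation_max_tries: int = 50,
        tournament_size: int = 2,
        random_state: int = 0,
    ) -> None:
        self.mode = mode
        self.subnetwork_size = subnetwork_size
        self.subnetwork_size2 = subnetwork_size2
        self.generations = generations
        self.population_size = population_size
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.mutation_max_tries = mutation_max_tries
        self.tournament_size = tournament_size
        self.random_state = random_state

    def _params(self) -> EAParameters:
        return EAParameters(
            generations=self.generations,
            population_size=self.population_size,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            subnetwork_size=self.subnetwork_size,
            subnetwork_size2=self.subnetwork_size2,
            mode=self.mode,
            seed=self.random_state,
            mutation_max_tries=self.mutation_max_tries,
            tournament_size=self.tournament_size,
        )

    def fit(self, network: ScoredNetwork, y=None) -> "EvolutionaryModuleFinder":
        if not isinstance(network, ScoredNetwork):
            raise TypeError("fit expects a ScoredNetwork")
        result = evolve(network, self._params())
        self.result_ = result
        self.best_fitness_ = result.best_fitness
        self.history_ = result.history
        self.best_module_ = network.labels_of(result.best.s1)
        self.best_module2_ = network.labels_of(result.best.s2)
        labels = np.zeros(network.n_nodes, dtype=int)
        for v in result.best.s1:
            labels[v] = 1
        if result.best.mode == "disjoint":
            for v in result.best.s2:
                labels[v] = 2
        self.labels_ = labels
        return self

    def fit_predict(self, network: ScoredNetwork, y=None) -> np.ndarray:
        return self.fit(network).labels_
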