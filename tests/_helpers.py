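"""Shared simulation/oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np

import lenscope as L
from lenscope.synthetic import PlantedSet


def null_de_run(seed: int, n_genes: int = 10320, n_per_group: int = 4,
                alpha: float = 0.1):
    """DE test on a matrix with no planted effects; returns the result table."""
    cfg = L.CountsSimConfig(
        n_genes=n_genes,
        group_sizes={"A": n_per_group, "B": n_per_group},
        dispersion_alpha=alpha,
        seed=seed,
    )
    sim = L.simulate_counts(cfg)
    return L.nb_de_test(sim.matrix, "A", "B")


def planted_recovery(seeds, n_planted: int = 200, log2_fold: float = 2.0,
                     min_baseline_cpm: float = 5.0):
    """Sensitivity (on well-expressed planted genes) and FDP per seed."""
    sens, fdps = [], []
    for seed in seeds:
        planted = PlantedSet("up", tuple(range(n_planted)), log2_fold, ("A",))
        cfg = L.CountsSimConfig(
            n_genes=10320,
            group_sizes={"A": 4, "B": 4},
            dispersion_alpha=0.1,
            planted_sets=(planted,),
            seed=seed,
        )
        sim = L.simulate_counts(cfg)
        de = L.nb_de_test(sim.matrix, "A", "B")
        table = de.table
        planted_ids = set(sim.truth.genes_of("up"))
        baseline_cpm = L.cpm(sim.matrix.subset_groups(["B"])).mean(axis=1)
        eligible = [
            g for g in planted_ids
            if g in table.index and baseline_cpm[g] >= min_baseline_cpm
        ]
        called = set(table.index[table["call"] != "ns"])
        sens.append(len(called & set(eligible)) / len(eligible))
        fdps.append(len(called - planted_ids) / max(1, len(called)))
    return np.array(sens), np.array(fdps)


def bh_stepup_oracle(pvalues: np.ndarray) -> np.ndarray:
    """Literal BH step-up adjusted p-values (independent of statsmodels)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for i in range(n - 1, -1, -1):
        rank = i + 1
        running_min = min(running_min, p[order[i]] * n / rank)
        adjusted[order[i]] = running_min
    return adjusted


def mc_null_overlap(n_total: int, k: int, n_draws: int, rng: np.random.Generator):
    """Monte-Carlo overlaps of the top-k of one fixed vs one permuted ranking."""
    base = np.arange(n_total)
    top_a = set(base[:k])
    overlaps = np.empty(n_draws)
    for i in range(n_draws):
        perm = rng.permutation(n_total)
        overlaps[i] = len(top_a.intersection(perm[:k]))
    return overlaps
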