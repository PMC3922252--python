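"""Replicated k-fold cross-validation of region kernels.

Each region's kernel is built once over all animals; within a fold the
sampler sees only the train x train block and the held-out animals are
scored by g_hat_test = K[test, train] alpha_hat. Predictive ability is the
Pearson correlation between preadjusted phenotypes and predicted additive
genetic values in the test set. The default design is 10 folds replicated
15 times with fresh random fold assignments per replicate.

Seeds for every (replicate, fold) cell derive from the master seed through
``numpy.random.SeedSequence(master, spawn_key=(replicate, fold))`` so any
single cell is reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernel import KernelMatrix
from .krr import MCMCConfig, PosteriorChain, PriorSpec, gibbs_krr, predict_genetic_values

__all__ = ["FoldPlan", "CVResult", "make_folds", "run_cv", "pearson",
           "summarize_relatedness"]


@dataclass
class FoldPlan:
    """Fold memberships: ``folds[replicate][fold]`` is an array of animal ids."""

    animal_ids: list[str]
    k: int
    replicates: int
    seed: int
    folds: list[list[np.ndarray]] = field(repr=False, default_factory=list)

    def test_ids(self, replicate: int, fold: int) -> np.ndarray:
        return self.folds[replicate][fold]


@dataclass
class CVResult:
    """Long-format fold correlations plus per-region summaries."""

    records: pd.DataFrame  # columns: region, replicate, fold, r, n_test

    def summary(self) -> pd.DataFrame:
        g = self.records.groupby("region")["r"]
        out = g.agg(mean="mean", q25=lambda s: s.quantile(0.25),
                    median="median", q75=lambda s: s.quantile(0.75))
        return out.reset_index()

    def replicate_means(self) -> pd.DataFrame:
        return (self.records.groupby(["region", "replicate"])["r"]
                .mean().reset_index())

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def make_folds(animal_ids, k: int = 10, replicates: int = 15, seed: int = 0) -> FoldPlan:
    """Random partitions into k disjoint subsets with sizes differing by <= 1."""
    animal_ids = list(animal_ids)
    n = len(animal_ids)
    if k > n:
        raise ValueError(f"cannot split {n} animals into {k} folds")
    plan = FoldPlan(animal_ids, k, replicates, seed)
    ids = np.array(animal_ids, dtype=object)
    for rep in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))
        perm = rng.permutation(n)
        plan.folds.append([ids[chunk] for chunk in np.array_split(perm, k)])
    return plan


def pearson(u, v) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 3:
        raise ValueError("pearson needs two equal-length vectors of length >= 3")
    if np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("correlation undefined for a constant vector")
    uc, vc = u - u.mean(), v - v.mean()
    return float((uc @ vc) / np.sqrt((uc @ uc) * (vc @ vc)))


def run_cv(
    kernel: KernelMatrix,
    y_R: np.ndarray | pd.Series,
    fold_plan: FoldPlan,
    priors: PriorSpec = PriorSpec(),
    mcmc: MCMCConfig = MCMCConfig.reduced(),
    region_name: str | None = None,
) -> CVResult:
    """Score one kernel by replicated k-fold predictive correlation.

    ``y_R`` must align with ``kernel.animal_ids`` (a named Series is
    reindexed). Folds with zero variance in either test phenotypes or
    predictions are recorded as missing with a warning.
    """
    ids = kernel.animal_ids
    if isinstance(y_R, pd.Series):
        y = y_R.reindex(ids).to_numpy(dtype=float)
    else:
        y = np.asarray(y_R, dtype=float)
    if len(y) != kernel.n or np.isnan(y).any():
        raise ValueError("y_R misaligned with kernel animals or contains NaN")
    if set(fold_plan.animal_ids) != set(ids):
        raise ValueError("fold plan and kernel cover different animals")
    pos = {a: i for i, a in enumerate(ids)}
    name = region_name or kernel.source or "kernel"
    rows = []
    for rep in range(fold_plan.replicates):
        for fold in range(fold_plan.k):
            test = np.array([pos[a] for a in fold_plan.test_ids(rep, fold)])
            train = np.setdiff1d(np.arange(kernel.n), test)
            sub_seed = int(np.random.SeedSequence(
                mcmc.seed, spawn_key=(rep, fold)).generate_state(1)[0] % (2 ** 31))
            cfg = MCMCConfig(mcmc.burn_in, mcmc.draws, mcmc.thin, sub_seed)
            chain = gibbs_krr(y[train], kernel.values[np.ix_(train, train)],
                              priors=priors, config=cfg)
            ghat_test = predict_genetic_values(
                kernel.values[np.ix_(test, train)], chain.alpha_hat)
            try:
                r = pearson(y[test], ghat_test)
            except ValueError:
                warnings.warn(
                    f"fold ({rep}, {fold}) of {name}: correlation undefined",
                    stacklevel=2)
                r = np.nan
            rows.append({"region": name, "replicate": rep, "fold": fold,
                         "r": r, "n_test": len(test)})
    return CVResult(pd.DataFrame(rows))


def summarize_relatedness(kernel: KernelMatrix, fold_plan: FoldPlan) -> pd.DataFrame:
    """Per-fold mean/median of the train x test block of the kernel.

    With in-sample centered G these summaries sit near or below zero,
    reflecting that a random test set is on average unrelated to (or
    slightly negatively related to) its training complement.
    """
    pos = {a: i for i, a in enumerate(kernel.animal_ids)}
    rows = []
    for rep in range(fold_plan.replicates):
        for fold in range(fold_plan.k):
            test = np.array([pos[a] for a in fold_plan.test_ids(rep, fold)])
            train = np.setdiff1d(np.arange(kernel.n), test)
            block = kernel.values[np.ix_(test, train)]
            rows.append({"replicate": rep, "fold": fold,
                         "mean": float(block.mean()),
                         "median": float(np.median(block))})
    return pd.DataFrame(rows)
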