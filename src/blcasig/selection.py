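"""Resampling gene-selection procedures built on DE + elastic-net fits.

Two complementary strategies stabilize the gene signature against the
randomness of a single train/test split:

* **Consensus frequency selection** repeats {stratified 70/30 split, DE
  on the training samples, cross-validated elastic-net fit} for a number
  of cycles (100 by default), counts how often each gene survives with a
  nonzero coefficient, and feeds the top-k most frequent genes into one
  final elastic-net fit on a fresh split.  This standardizes the *genes*.

* **Maximum-overlap selection** standardizes the *patients*: phase 1
  builds a gene pool from repeated elastic-net fits on the full cohort
  (DE at a laxer alpha = 0.05, cycle-to-cycle variation coming only from
  CV fold randomization); phase 2 generates candidate models on random
  70/30 splits (DE at alpha = 0.01) and ``find_overlap`` scans them in
  order, keeping a candidate only when its gene overlap with the pool
  strictly increases while its test accuracy does not decrease.  The
  winning split is frozen and the final model refit on it.

Per-cycle randomness derives from the master seed through SeedSequence
spawning, so both procedures are fully reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dge import de_select
from .enet import (
    ElasticNetLogistic,
    SplitSpec,
    accuracy_ci,
    roc_auc,
    stratified_split,
)
from .exceptions import DomainError, EmptyConsensusError
from .ingest import Cohort


@dataclass
class CandidateModel:
    """One resampled model: fit, split, nonzero genes, test accuracy."""

    fit: ElasticNetLogistic
    split: SplitSpec
    genes: frozenset[str]
    accuracy: float


@dataclass
class SelectionOutcome:
    """Result of either selection procedure."""

    mode: str                                   # "consensus" | "max_overlap"
    signature: list[str]                        # final nonzero gene set
    final_fit: ElasticNetLogistic
    split: SplitSpec
    accuracy: float
    accuracy_ci: tuple[float, float, float]
    auc: float
    frequencies: pd.Series | None = None        # consensus only
    gene_pool: frozenset[str] | None = None     # max-overlap only
    best_candidate: CandidateModel | None = None
    overlap_size: int | None = None
    cycles: int = 0


def find_overlap(candidates: list[CandidateModel],
                 pool: frozenset[str] | set[str]) -> CandidateModel:
    """Sequential scan for the best overlap/accuracy trade-off.

    The first candidate initializes the incumbent; a later candidate
    replaces it only when its gene overlap with ``pool`` is strictly
    larger AND its accuracy is not worse than the incumbent's.
    """
    if not candidates:
        raise DomainError("candidate list is empty")
    pool = frozenset(pool)
    incumbent = candidates[0]
    best_overlap = len(incumbent.genes & pool)
    for cand in candidates[1:]:
        overlap = len(cand.genes & pool)
        if overlap > best_overlap and cand.accuracy >= incumbent.accuracy:
            incumbent, best_overlap = cand, overlap
    return incumbent


def _spawn_seeds(random_state: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(random_state)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def _check_endpoint(y: pd.Series) -> pd.Series:
    y = pd.Series(y).astype(int)
    counts = y.value_counts()
    if len(counts) != 2 or counts.min() < 4:
        raise DomainError("endpoint must be binary with at least 4 samples per class")
    return y


def _evaluate(fit: ElasticNetLogistic, X_test: pd.DataFrame, y_test: pd.Series):
    p = fit.predict_proba(X_test)[:, 1]
    pred = (p > 0.5).astype(int)
    correct = int((pred == y_test.to_numpy()).sum())
    acc, lo, hi = accuracy_ci(correct, len(y_test))
    try:
        auc = roc_auc(p, y_test.to_numpy()).auc
    except DomainError:
        auc = float("nan")
    return p, acc, (acc, lo, hi), auc


class ConsensusGeneSelector(BaseEstimator, TransformerMixin):
    """Consensus frequency gene selection (gene-standardizing procedure).

    ``fit(X, y)`` expects samples x genes.  Fitted attributes:
    ``frequencies_`` (per-gene nonzero counts over cycles), ``ranking_``
    (count descending, gene ID ascending), ``top_genes_``, ``signature_``
    (final model's nonzero genes), ``final_model_``, ``split_``,
    ``accuracy_``, ``accuracy_ci_``, ``auc_``, ``outcome_``.
    """

    def __init__(self, cycles: int = 100, alpha: float = 0.01,
                 cutoff: float = 0.7, top_k: int = 100, ratio: float = 0.7,
                 cv: int = 10, mixing: float = 0.5, n_lambdas: int = 100,
                 random_state: int | None = None):
        self.cycles = cycles
        self.alpha = alpha
        self.cutoff = cutoff
        self.top_k = top_k
        self.ratio = ratio
        self.cv = cv
        self.mixing = mixing
        self.n_lambdas = n_lambdas
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = _check_endpoint(pd.Series(np.asarray(y).astype(int), index=X.index))
        seeds = _spawn_seeds(self.random_state, self.cycles + 1)
        counter: Counter[str] = Counter()
        for c in range(self.cycles):
            split = stratified_split(y, self.ratio, seed=seeds[c])
            tr = list(split.train_ids)
            de = de_select(X.loc[tr].T, y.loc[tr], alpha=self.alpha,
                           cutoff=self.cutoff)
            genes = de.selected_genes
            if not genes:
                continue
            model = ElasticNetLogistic(mixing=self.mixing, cv=self.cv,
                                       n_lambdas=self.n_lambdas,
                                       random_state=seeds[c])
            model.fit(X.loc[tr, genes], y.loc[tr])
            counter.update(model.nonzero_genes_)
        if not counter:
            raise EmptyConsensusError(
                "no gene was selected in any cycle (empty consensus)")
        freq = pd.Series(counter, dtype=int)
        ranking = freq.sort_index().sort_values(ascending=False, kind="stable")
        top = list(ranking.index[: self.top_k])

        final_seed = seeds[self.cycles]
        split = stratified_split(y, self.ratio, seed=final_seed)
        tr, te = list(split.train_ids), list(split.test_ids)
        final = ElasticNetLogistic(mixing=self.mixing, cv=self.cv,
                                   n_lambdas=self.n_lambdas,
                                   random_state=final_seed)
        final.fit(X.loc[tr, top], y.loc[tr])
        _, acc, ci, auc = _evaluate(final, X.loc[te, top], y.loc[te])

        self.frequencies_ = freq
        self.ranking_ = ranking
        self.top_genes_ = top
        self.final_model_ = final
        self.split_ = split
        self.signature_ = list(final.nonzero_genes_)
        self.accuracy_ = acc
        self.accuracy_ci_ = ci
        self.auc_ = auc
        self.outcome_ = SelectionOutcome(
            mode="consensus", signature=self.signature_, final_fit=final,
            split=split, accuracy=acc, accuracy_ci=ci, auc=auc,
            frequencies=ranking, cycles=self.cycles,
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "signature_")
        return pd.DataFrame(X)[self.signature_]


def collect_gene_pool(X: pd.DataFrame, y: pd.Series, cycles: int = 100,
                      alpha: float = 0.05, cutoff: float = 0.7,
                      cv: int = 10, mixing: float = 0.5,
                      n_lambdas: int = 100,
                      random_state: int | None = None) -> frozenset[str]:
    """Union of nonzero genes over repeated full-cohort elastic-net fits.

    The DE step runs once on the full cohort at the laxer ``alpha``; the
    per-cycle variation comes from CV fold randomization only, and any
    gene selected even once enters the pool.
    """
    X = pd.DataFrame(X)
    y = _check_endpoint(pd.Series(np.asarray(y).astype(int), index=X.index))
    de = de_select(X.T, y, alpha=alpha, cutoff=cutoff)
    genes = de.selected_genes
    if not genes:
        raise EmptyConsensusError("DE stage selected no genes on the full cohort")
    seeds = _spawn_seeds(random_state, cycles)
    pool: set[str] = set()
    for c in range(cycles):
        model = ElasticNetLogistic(mixing=mixing, cv=cv, n_lambdas=n_lambdas,
                                   random_state=seeds[c])
        model.fit(X[genes], y)
        pool.update(model.nonzero_genes_)
    return frozenset(pool)


class MaxOverlapSelector(BaseEstimator, TransformerMixin):
    """Maximum-overlap sample-and-gene selection (patient-standardizing).

    Fitted attributes: ``pool_``, ``candidates_``, ``best_``,
    ``overlap_size_``, ``signature_``, ``final_model_``, ``split_``,
    ``accuracy_``, ``accuracy_ci_``, ``auc_``, ``outcome_``.
    """

    def __init__(self, cycles: int = 100, phase1_cycles: int | None = None,
                 alpha_phase1: float = 0.05, alpha_phase2: float = 0.01,
                 cutoff: float = 0.7, ratio: float = 0.7, cv: int = 10,
                 mixing: float = 0.5, n_lambdas: int = 100,
                 random_state: int | None = None):
        self.cycles = cycles
        self.phase1_cycles = phase1_cycles
        self.alpha_phase1 = alpha_phase1
        self.alpha_phase2 = alpha_phase2
        self.cutoff = cutoff
        self.ratio = ratio
        self.cv = cv
        self.mixing = mixing
        self.n_lambdas = n_lambdas
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = _check_endpoint(pd.Series(np.asarray(y).astype(int), index=X.index))
        p1 = self.cycles if self.phase1_cycles is None else self.phase1_cycles
        seeds = _spawn_seeds(self.random_state, self.cycles + 2)

        pool = collect_gene_pool(
            X, y, cycles=p1, alpha=self.alpha_phase1, cutoff=self.cutoff,
            cv=self.cv, mixing=self.mixing, n_lambdas=self.n_lambdas,
            random_state=seeds[-1],
        )

        candidates: list[CandidateModel] = []
        for c in range(self.cycles):
            split = stratified_split(y, self.ratio, seed=seeds[c])
            tr, te = list(split.train_ids), list(split.test_ids)
            de = de_select(X.loc[tr].T, y.loc[tr], alpha=self.alpha_phase2,
                           cutoff=self.cutoff)
            genes = de.selected_genes
            if not genes:
                continue
            model = ElasticNetLogistic(mixing=self.mixing, cv=self.cv,
                                       n_lambdas=self.n_lambdas,
                                       random_state=seeds[c])
            model.fit(X.loc[tr, genes], y.loc[tr])
            pred = model.predict(X.loc[te, genes])
            acc = float(np.mean(pred == y.loc[te].to_numpy()))
            candidates.append(CandidateModel(
                fit=model, split=split,
                genes=frozenset(model.nonzero_genes_), accuracy=acc))
        if not candidates:
            raise EmptyConsensusError(
                "no cycle produced a candidate model (empty consensus)")

        best = find_overlap(candidates, pool)

        # freeze the winning split and refit the final model on it
        tr = list(best.split.train_ids)
        te = list(best.split.test_ids)
        de = de_select(X.loc[tr].T, y.loc[tr], alpha=self.alpha_phase2,
                       cutoff=self.cutoff)
        genes = de.selected_genes
        final = ElasticNetLogistic(mixing=self.mixing, cv=self.cv,
                                   n_lambdas=self.n_lambdas,
                                   random_state=seeds[self.cycles])
        final.fit(X.loc[tr, genes], y.loc[tr])
        _, acc, ci, auc = _evaluate(final, X.loc[te, genes], y.loc[te])

        self.pool_ = pool
        self.candidates_ = candidates
        self.best_ = best
        self.overlap_size_ = len(best.genes & pool)
        self.final_model_ = final
        self.split_ = best.split
        self.signature_ = list(final.nonzero_genes_)
        self.accuracy_ = acc
        self.accuracy_ci_ = ci
        self.auc_ = auc
        self.outcome_ = SelectionOutcome(
            mode="max_overlap", signature=self.signature_, final_fit=final,
            split=best.split, accuracy=acc, accuracy_ci=ci, auc=auc,
            gene_pool=pool, best_candidate=best,
            overlap_size=self.overlap_size_, cycles=self.cycles,
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "signature_")
        return pd.DataFrame(X)[self.signature_]


# -- cohort-level wrappers -------------------------------------------------

def consensus_select(cohort: Cohort, endpoint: str, cycles: int = 100,
                     alpha: float = 0.01, top_k: int = 100,
                     seed: int | None = None, **kwargs) -> SelectionOutcome:
    """Run consensus selection on a cohort endpoint."""
    sel = ConsensusGeneSelector(cycles=cycles, alpha=alpha, top_k=top_k,
                                random_state=seed, **kwargs)
    sel.fit(cohort.expression.T, cohort.endpoint(endpoint))
    return sel.outcome_


def max_overlap_select(cohort: Cohort, endpoint: str, cycles: int = 100,
                       alpha_phase2: float = 0.01, ratio: float = 0.7,
                       seed: int | None = None, **kwargs) -> SelectionOutcome:
    """Run maximum-overlap selection on a cohort endpoint."""
    sel = MaxOverlapSelector(cycles=cycles, alpha_phase2=alpha_phase2,
                             ratio=ratio, random_state=seed, **kwargs)
    sel.fit(cohort.expression.T, cohort.endpoint(endpoint))
    return sel.outcome_
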