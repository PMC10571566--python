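"""Differential expression: mean filter, Wilcoxon rank-sum, OR-rule selection.

The stage deliberately avoids count-model packages: expression values are
continuous, normalized, and outlier-prone, so a nonparametric rank test
is used per gene.  Genes whose mean expression over all samples falls
below a cutoff (default 0.7) are removed first; each surviving gene is
then tested with the Wilcoxon rank-sum (Mann-Whitney U) test in both
one-sided directions, and a gene is selected when either one-sided
p-value falls at or below the significance level alpha.  No
multiple-testing correction is applied; selection feeds a regularized
model rather than being reported as an inference in its own right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DomainError

_EXACT_MAX_N = 25  # exact rank-sum distribution up to this group size (no ties)


def mean_filter(expression: pd.DataFrame, cutoff: float = 0.7) -> pd.DataFrame:
    """Keep genes whose mean expression across all samples is >= ``cutoff``.

    The boundary is inclusive: the cutoff is a floor under which genes are
    considered uninformative near-zero mass, while still low enough that
    strongly inhibited but present genes pass.
    """
    if cutoff < 0:
        raise DomainError(f"cutoff must be non-negative, got {cutoff}")
    if expression.shape[0] == 0:
        return expression
    keep = expression.mean(axis=1) >= cutoff
    return expression.loc[keep]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Both one-sided Wilcoxon rank-sum p-values for group x vs group y.

    Returns ``(p_over, p_under)``: the p-value that x is stochastically
    higher than y, and that it is lower.  The exact null distribution is
    used when both groups have at most 25 observations and no ties are
    present; otherwise the normal approximation with tie-corrected
    variance and a 0.5 continuity correction applies.  If every value in
    both groups is identical, both p-values are 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N
                         and not has_ties) else "asymptotic"
    p_over = stats.mannwhitneyu(x, y, alternative="greater", method=method,
                                use_continuity=True).pvalue
    p_under = stats.mannwhitneyu(x, y, alternative="less", method=method,
                                 use_continuity=True).pvalue
    return float(p_over), float(p_under)


@dataclass
class DEResult:
    """Per-gene one-sided p-value pair and the OR-rule selection flag.

    ``table`` has one row per gene surviving the mean filter, in input
    order, with columns ``p_over``, ``p_under`` and ``selected``.
    """

    table: pd.DataFrame
    alpha: float
    cutoff: float

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


class WilcoxonDESelector(BaseEstimator, TransformerMixin):
    """Feature selector: mean filter then two-sided-pair Wilcoxon tests.

    Parameters
    ----------
    alpha : significance level for the one-sided p-values (default 0.01).
    cutoff : mean-expression floor applied before testing (default 0.7).

    The estimator follows the scikit-learn convention of samples-as-rows:
    ``fit(X, y)`` expects ``X`` of shape (n_samples, n_genes) and binary
    ``y`` where 1 is the event-positive group; ``p_over`` is the p-value
    that a gene is *higher* in that group.
    """

    def __init__(self, alpha: float = 0.01, cutoff: float = 0.7):
        self.alpha = alpha
        self.cutoff = cutoff

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        if X.shape[0] != y.size:
            raise DomainError("X and y have mismatched sample counts")
        classes = np.unique(y)
        if classes.size != 2 or not set(classes) <= {0, 1}:
            raise DomainError("y must contain both classes coded 0/1")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        values = X.to_numpy(dtype=float)
        self.means_ = values.mean(axis=0)
        mean_mask = self.means_ >= self.cutoff

        p_over = np.full(X.shape[1], np.nan)
        p_under = np.full(X.shape[1], np.nan)
        pos = values[y == 1]
        neg = values[y == 0]
        idx = np.flatnonzero(mean_mask)
        if idx.size:
            if pos.shape[0] > _EXACT_MAX_N or neg.shape[0] > _EXACT_MAX_N:
                # large-sample: vectorized normal approximation across genes
                res_g = stats.mannwhitneyu(pos[:, idx], neg[:, idx], axis=0,
                                           alternative="greater",
                                           method="asymptotic",
                                           use_continuity=True)
                res_l = stats.mannwhitneyu(pos[:, idx], neg[:, idx], axis=0,
                                           alternative="less",
                                           method="asymptotic",
                                           use_continuity=True)
                p_over[idx] = res_g.pvalue
                p_under[idx] = res_l.pvalue
                constant = np.ptp(values[:, idx], axis=0) == 0
                p_over[idx[constant]] = 1.0
                p_under[idx[constant]] = 1.0
            else:
                for j in idx:
                    p_over[j], p_under[j] = wilcoxon_rank_sum(pos[:, j], neg[:, j])
        self.p_over_ = p_over
        self.p_under_ = p_under
        self.mean_mask_ = mean_mask
        self.support_ = mean_mask & (
            np.nan_to_num(p_over, nan=1.0) <= self.alpha
        ) | mean_mask & (np.nan_to_num(p_under, nan=1.0) <= self.alpha)
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_.copy()

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = pd.DataFrame(X)
        return X.loc[:, self.support_]

    def result(self) -> DEResult:
        """The per-gene table for genes surviving the mean filter."""
        check_is_fitted(self, "support_")
        idx = self.mean_mask_
        table = pd.DataFrame(
            {
                "p_over": self.p_over_[idx],
                "p_under": self.p_under_[idx],
                "selected": self.support_[idx],
            },
            index=pd.Index(self.feature_names_in_[idx], name="gene_id"),
        )
        return DEResult(table=table, alpha=self.alpha, cutoff=self.cutoff)


def de_select(expression: pd.DataFrame, groups, alpha: float = 0.01,
              cutoff: float = 0.7) -> DEResult:
    """Run the full DE stage on a genes x samples matrix.

    ``groups`` gives the binary endpoint per sample (aligned with the
    expression columns); group 1 is the event-positive class.
    """
    groups = pd.Series(np.asarray(groups), index=expression.columns)
    if groups.nunique() < 2:
        raise DomainError("grouping must contain both classes")
    sel = WilcoxonDESelector(alpha=alpha, cutoff=cutoff)
    sel.fit(expression.T, groups.to_numpy())
    return sel.result()
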