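"""Detection metrics (confusion, F1, sensitivity/specificity, rank AUC) and
the Wilcoxon rank-sum differential-expression test used by the experiment
designs."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(predicted, truth, N: int) -> ConfusionCounts:
    """2x2 counts for rare-vs-not over N cells."""
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = N - tp - fp - fn
    if tn < 0:
        raise ValueError("predicted/truth sets exceed the stated population size")
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def f1_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both are undefined/zero."""
    if c.TP == 0:
        return 0.0
    precision = c.TP / (c.TP + c.FP)
    recall = c.TP / (c.TP + c.FN)
    return 2.0 * precision * recall / (precision + recall)


def sensitivity_specificity(c: ConfusionCounts) -> tuple:
    """(TP/(TP+FN), TN/(TN+FP)); an undefined ratio is reported as None."""
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else None
    return sens, spec


def rank_auc(scores, truth) -> float:
    """P(random positive outranks random negative), ties counted half.

    ``scores`` is an array over all cells; ``truth`` is a boolean mask or a
    set of positive indices.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if isinstance(truth, (set, frozenset, list, tuple)) or (
        isinstance(truth, np.ndarray) and truth.dtype != bool
    ):
        mask = np.zeros(scores.size, dtype=bool)
        mask[np.asarray(list(truth), dtype=np.int64)] = True
    else:
        mask = np.asarray(truth, dtype=bool)
    n_pos = int(mask.sum())
    n_neg = scores.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("rank_auc needs at least one positive and one negative")
    ranks = stats.rankdata(scores, method="average")
    return float((ranks[mask].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact below 50 tie-free observations, otherwise
    normal approximation with continuity and tie correction."""
    if np.ptp(np.concatenate((x, y))) == 0:
        return 1.0
    combined = np.concatenate((x, y))
    exact = combined.size < 50 and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def wilcoxon_de(
    norm: NormalizedMatrix,
    group_a,
    group_b,
    fdr: float = 0.05,
    lfc: float = 1.0,
    raw_counts=None,
    min_count: int = 2,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-gene rank-sum DE test between two cell groups.

    log2FC is the difference of group means of the log-normalised values;
    p-values are Benjamini-Hochberg adjusted and a gene is flagged when
    adjusted p < ``fdr`` and |log2FC| > ``lfc``.  If ``raw_counts`` is given,
    genes with counts > ``min_count`` in fewer than ``min_cells`` cells are
    excluded before testing (the pre-filter used by the replacement design).
    """
    cell_pos = {c: i for i, c in enumerate(norm.cell_ids)}
    ia = np.array([cell_pos[str(c)] for c in group_a])
    ib = np.array([cell_pos[str(c)] for c in group_b])
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both groups need at least 2 cells")

    genes = np.arange(norm.gene_ids.size)
    if raw_counts is not None:
        raw_counts = np.asarray(raw_counts)
        keep = (raw_counts[:, np.concatenate((ia, ib))] > min_count).sum(axis=1) >= min_cells
        genes = genes[keep]

    values = norm.values
    lfc_vals = values[np.ix_(genes, ia)].mean(axis=1) - values[np.ix_(genes, ib)].mean(axis=1)
    pvals = np.array([_rank_sum_p(values[g, ia], values[g, ib]) for g in genes])
    padj = multipletests(pvals, method="fdr_bh")[1] if pvals.size else pvals
    flags = (padj < fdr) & (np.abs(lfc_vals) > lfc)
    return pd.DataFrame(
        {
            "gene": norm.gene_ids[genes],
            "log2fc": lfc_vals,
            "pvalue": pvals,
            "padj": padj,
            "de": flags,
        }
    ).set_index("gene")
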