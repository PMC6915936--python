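"""Per-sample cell-type signature scores from marker gene sets.

A transparent single-sample rank-enrichment scorer: per sample, genes are
ranked by expression and each gene set gets a normalized weighted
Kolmogorov-Smirnov running-sum statistic (the single-sample gene-set
enrichment form).  Scores depend on within-sample ranks only, so any
strictly increasing transform of one sample's expression leaves its scores
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import ExpressionMatrix, GeneSetCollection, UsageError, ValidationError

logger = logging.getLogger("gmicnet")


@dataclass
class SignatureScores:
    """samples x signatures score table; ``scaled`` marks per-signature
    z-scoring across samples."""

    data: pd.DataFrame
    scaled: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def signature_names(self) -> list[str]:
        return list(self.data.columns)


def _sample_enrichment(order: np.ndarray, weights: np.ndarray,
                       in_set: np.ndarray) -> float:
    """ssGSEA-style running-sum enrichment for one sample.

    ``order`` walks genes in decreasing expression; ``weights`` are the
    rank-score weights aligned to gene index; ``in_set`` flags membership.
    The statistic integrates the gap between the weighted hit CDF and the
    uniform miss CDF, normalized by gene count, so it lies in (-1, 1).
    """
    n = order.size
    hits = in_set[order]
    w = weights[order] * hits
    denom_hit = w.sum()
    n_miss = n - int(in_set.sum())
    p_hit = np.cumsum(w) / denom_hit
    p_miss = np.cumsum(~hits) / n_miss if n_miss > 0 else np.zeros(n)
    return float((p_hit - p_miss).sum() / n)


def score_signatures(x: ExpressionMatrix, sets: GeneSetCollection,
                     alpha: float = 0.25,
                     case_insensitive: bool = False) -> SignatureScores:
    """Single-sample rank-enrichment score of every gene set in every sample.

    Per sample, genes are ranked by descending expression (ties get average
    rank; walk order ties break by gene id) and weighted by rank^alpha.
    Sets sharing fewer than 3 genes with the matrix are skipped with a
    warning; if no set matches, a validation error is raised.
    """
    if not 0 < alpha <= 1:
        raise UsageError("alpha must be in (0, 1]")
    genes = np.array(x.gene_ids)
    lookup = {g.lower() if case_insensitive else g: i for i, g in enumerate(genes)}
    memberships: dict[str, np.ndarray] = {}
    for name in sets.names():
        members = sets.members(name)
        idx = [lookup[m.lower() if case_insensitive else m]
               for m in members if (m.lower() if case_insensitive else m) in lookup]
        if len(idx) < 3:
            logger.warning("score_signatures: set %r shares %d (<3) genes with the "
                           "matrix; skipped", name, len(idx))
            continue
        flag = np.zeros(len(genes), dtype=bool)
        flag[idx] = True
        memberships[name] = flag
    if not memberships:
        raise ValidationError("no gene set shares >= 3 genes with the expression matrix")

    values = x.values
    n_genes, n_samples = values.shape
    out = np.zeros((n_samples, len(memberships)))
    for j in range(n_samples):
        col = values[:, j]
        # walk order: descending expression, ties by gene id
        order = np.lexsort((genes, -col))
        weights = rankdata(col) ** alpha     # ascending rank, average ties
        for s, flag in enumerate(memberships.values()):
            out[j, s] = _sample_enrichment(order, weights, flag)
    data = pd.DataFrame(out, index=pd.Index(x.sample_ids),
                        columns=list(memberships))
    return SignatureScores(data, scaled=False)


def scale_scores(s: SignatureScores) -> SignatureScores:
    """Center and scale each signature to mean 0, sample sd 1 across samples.

    Zero-variance signatures are dropped with a warning.  Idempotent up to
    floating-point tolerance.
    """
    if s.data.shape[0] < 2:
        raise UsageError("scaling needs at least 2 samples")
    sd = s.data.std(ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("scale_scores: dropping %d zero-variance signatures: %s",
                       int((~keep).sum()), list(sd.index[~keep])[:5])
    data = s.data.loc[:, keep]
    scaled = (data - data.mean()) / data.std(ddof=1)
    return SignatureScores(scaled, scaled=True)
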