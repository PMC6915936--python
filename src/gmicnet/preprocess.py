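"""Matrix cleaning: low-frequency gene removal and outlier-sample detection.

Two conservative steps applied before network construction: genes that are
zero in more than a configurable fraction of samples are dropped, and
samples that fall into small clusters of an average-linkage dendrogram can
be flagged as outliers.  Outlier flagging is opt-in (no cut height means
nothing is flagged) and the merge heights are always reported so the cut
can be chosen by inspection rather than silently.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .data_io import ExpressionMatrix, UsageError, ValidationError

logger = logging.getLogger("gmicnet")


def filter_low_frequency_genes(x: ExpressionMatrix,
                               max_zero_fraction: float = 0.9) -> ExpressionMatrix:
    """Drop genes whose zero fraction strictly exceeds ``max_zero_fraction``.

    The boundary is strict: a gene zero in exactly 90% of samples survives a
    0.9 threshold.  Sample set and surviving gene order are unchanged.
    """
    if not 0 < max_zero_fraction < 1:
        raise UsageError("max_zero_fraction must be in (0, 1)")
    zero_frac = (x.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        raise ValidationError(
            "all genes exceed the zero-fraction threshold; lower max_zero_fraction")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_low_frequency_genes: removed %d of %d genes",
                    dropped, len(keep))
    return ExpressionMatrix(x.data.loc[keep])


def sample_merge_heights(x: ExpressionMatrix) -> np.ndarray:
    """Merge heights of the average-linkage sample dendrogram (ascending)."""
    return _sample_linkage(x)[:, 2]


def _sample_linkage(x: ExpressionMatrix) -> np.ndarray:
    values = x.values  # genes x samples
    sd = values.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.any():
        raise ValidationError("no gene has nonzero variance; cannot cluster samples")
    z = (values[usable] - values[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
    dist = pdist(z.T, metric="euclidean")
    return linkage(dist, method="average")


def detect_outlier_samples(x: ExpressionMatrix,
                           cut_height: float | None = None,
                           min_cluster: int = 2) -> list[str]:
    """Flag samples in dendrogram clusters smaller than ``min_cluster``.

    Samples are clustered by average linkage on Euclidean distance over
    per-gene standardized expression; the tree is cut at ``cut_height``.
    ``cut_height=None`` (the default) flags nothing — the caller should pick
    a cut from :func:`sample_merge_heights`.
    """
    if x.shape[1] < 3:
        raise UsageError("need at least 3 samples for outlier detection")
    if cut_height is None:
        return []
    if cut_height <= 0:
        raise UsageError("cut_height must be positive")
    lk = _sample_linkage(x)
    labels = fcluster(lk, t=cut_height, criterion="distance")
    sizes = np.bincount(labels)
    flagged = [s for s, lab in zip(x.sample_ids, labels) if sizes[lab] < min_cluster]
    if flagged:
        logger.info("detect_outlier_samples: flagged %d samples at cut %.3g: %s",
                    len(flagged), cut_height, flagged)
    return flagged


def drop_samples(x: ExpressionMatrix, sample_ids: list[str]) -> ExpressionMatrix:
    """Return a copy of ``x`` with the listed samples removed."""
    keep = [s for s in x.sample_ids if s not in set(sample_ids)]
    if not keep:
        raise ValidationError("dropping these samples would empty the matrix")
    return ExpressionMatrix(x.data[keep])
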