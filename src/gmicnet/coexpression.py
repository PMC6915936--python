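"""Weighted co-expression network: bicor, signed-hybrid adjacency, TOM,
module detection, eigengenes and connectivity.

The network is built from biweight midcorrelation (robust to single
outliers), raised to a soft power with negative correlations zeroed (the
"signed hybrid" convention), converted to topological overlap, and cut into
modules by average-linkage clustering.  Each module is summarized by its
eigengene — the first principal component of the standardized module
submatrix — and close modules (eigengene dissimilarity below a merge
height) are collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix, RunConfig, UsageError, ValidationError

logger = logging.getLogger("gmicnet")

_SYM_TOL = 1e-10


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    node_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.node_ids):
            raise ValidationError("correlation matrix shape/id mismatch")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValidationError("correlation matrix is not symmetric")
        if np.abs(v).max(initial=0.0) > 1 + 1e-12:
            raise ValidationError("correlation values outside [-1, 1]")
        if np.abs(np.diag(v) - 1).max(initial=0.0) > 1e-10:
            raise ValidationError("correlation diagonal must be 1")


@dataclass
class AdjacencyMatrix:
    """Signed-hybrid adjacency; ``values`` has zero diagonal (the
    connectivity view).  ``with_unit_diagonal`` exposes the TOM-input view."""

    node_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.node_ids):
            raise ValidationError("adjacency matrix shape/id mismatch")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValidationError("adjacency matrix is not symmetric")
        if v.min(initial=0.0) < 0 or v.max(initial=0.0) > 1 + 1e-12:
            raise ValidationError("adjacency values outside [0, 1]")

    def with_unit_diagonal(self) -> np.ndarray:
        out = self.values.copy()
        np.fill_diagonal(out, 1.0)
        return out


@dataclass
class ModuleAssignment:
    """gene -> module index (0 = unassigned) plus per-gene connectivity."""

    modules: "pd.Series[int]"
    stats: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.modules.index)

    def module_indices(self) -> list[int]:
        return sorted(m for m in self.modules.unique() if m != 0)

    def genes_in(self, module: int) -> list[str]:
        return list(self.modules.index[self.modules == module])

    def n_modules(self) -> int:
        return len(self.module_indices())


@dataclass
class EigengeneTable:
    """samples x modules table of eigengenes plus per-module variance explained.

    Columns are named ``ME<module_index>``.  Each eigengene has unit sample
    variance and non-negative correlation with its module's mean
    standardized expression.
    """

    data: pd.DataFrame
    variance_explained: dict[int, float] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def module_indices(self) -> list[int]:
        return [int(c[2:]) for c in self.data.columns]


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_prepare(rows: np.ndarray) -> np.ndarray:
    """Per row: median-center, Tukey-biweight downweight, unit-normalize.

    Rows whose median absolute deviation is zero fall back to the Pearson
    transform (mean-centering, no weights); the fallback is logged.  A
    zero-variance row yields NaNs, reported by the callers.
    """
    rows = np.asarray(rows, dtype=float)
    med = np.median(rows, axis=1, keepdims=True)
    dev = rows - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = (mad == 0).ravel()
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = dev / (9.0 * safe_mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    out = dev * w
    if fallback.any():
        logger.debug("bicor: Pearson fallback for %d of %d vectors (MAD = 0)",
                     int(fallback.sum()), rows.shape[0])
        out[fallback] = rows[fallback] - rows[fallback].mean(axis=1, keepdims=True)
    norm = np.sqrt((out ** 2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = out / norm
    out[norm.ravel() == 0] = np.nan
    return out


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors, in [-1, 1].

    Deviations from the median are downweighted by the Tukey biweight
    ``(1 - u^2)^2`` with ``u = (x - median) / (9 MAD)``; points beyond
    ``|u| >= 1`` get zero weight.  Falls back to Pearson when MAD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UsageError("bicor: length mismatch")
    if x.size < 3:
        raise UsageError("bicor: need at least 3 observations")
    t = _bicor_prepare(np.vstack([x, y]))
    if np.isnan(t).any():
        raise ValidationError("bicor: undefined correlation for zero-variance vector")
    return float(np.clip(t[0] @ t[1], -1.0, 1.0))


def bicor_matrix(x: ExpressionMatrix) -> CorrelationMatrix:
    """All-pairs biweight midcorrelation over genes.

    Zero-variance genes cannot be correlated; they are excluded from the
    matrix with a logged warning (callers assign them module 0).
    """
    t = _bicor_prepare(x.values)
    bad = np.isnan(t).any(axis=1)
    ids = list(x.gene_ids)
    if bad.any():
        dropped = [g for g, b in zip(ids, bad) if b]
        logger.warning("bicor_matrix: excluding %d zero-variance genes: %s",
                       len(dropped), dropped[:5])
        t = t[~bad]
        ids = [g for g, b in zip(ids, bad) if not b]
    c = np.clip(t @ t.T, -1.0, 1.0)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(ids, c)


# ---------------------------------------------------------------------------
# adjacency, soft-threshold diagnostics, TOM
# ---------------------------------------------------------------------------

def signed_hybrid_adjacency(c: CorrelationMatrix, beta: float) -> AdjacencyMatrix:
    """a_ij = cor_ij^beta for positive correlations, 0 otherwise."""
    if beta < 1:
        raise UsageError("soft power beta must be >= 1")
    a = np.where(c.values > 0, np.power(np.maximum(c.values, 0.0), beta), 0.0)
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(c.node_ids, a)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log degree-distribution fit, and mean k.

    Connectivities are binned on log10(k) (equal-width bins); the linear fit
    of log10 p(k) against the log10 mean connectivity per bin gives R^2,
    reported with the sign of the slope folded in so scale-free (negative
    slope) topology scores positively.
    """
    k = np.asarray(k, dtype=float)
    mean_k = float(k.mean())
    k = k[k > 0]
    if k.size < 3:
        return 0.0, mean_k
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        p = mask.mean()
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(p))
    if len(xs) < 3:
        return 0.0, mean_k
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = np.array(ys) - (slope * np.array(xs) + intercept)
    ss_tot = ((np.array(ys) - np.mean(ys)) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), mean_k


def pick_soft_threshold(c: CorrelationMatrix,
                        powers: list[int] | None = None) -> pd.DataFrame:
    """Scale-free fit diagnostics across candidate soft powers.

    Returns a table with columns ``power``, ``scale_free_r2`` (signed) and
    ``mean_k``; the caller picks the lowest power reaching a satisfactory
    fit (the pipeline default is 5).
    """
    if powers is None:
        powers = list(range(1, 13))
    if len(c.node_ids) < 20:
        raise UsageError("pick_soft_threshold needs >= 20 nodes for a meaningful fit")
    if not (c.values[~np.eye(len(c.node_ids), dtype=bool)] > 0).any():
        raise ValidationError("degenerate network: no positive correlations")
    rows = []
    for p in powers:
        adj = signed_hybrid_adjacency(c, p)
        k = adj.values.sum(axis=1)
        r2, mean_k = scale_free_fit(k)
        rows.append({"power": p, "scale_free_r2": r2, "mean_k": mean_k})
    return pd.DataFrame(rows)


def tom_similarity(a: AdjacencyMatrix) -> np.ndarray:
    """Topological overlap: shared-neighbor similarity in [0, 1], diag 1.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij); with the
    zero-diagonal adjacency the matrix product already excludes u = i, j.
    """
    av = a.values
    k = av.sum(axis=1)
    num = av @ av + av
    denom = np.minimum.outer(k, k) + 1.0 - av
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# module detection and merging
# ---------------------------------------------------------------------------

def _relabel_by_size(labels: np.ndarray, min_module_size: int) -> np.ndarray:
    """Send clusters below the size floor to 0; relabel the rest 1..M by
    decreasing size (ties by smallest original label for determinism)."""
    out = np.zeros_like(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    keep = [(int(cnt), int(lab)) for lab, cnt in zip(uniq, counts) if cnt >= min_module_size]
    keep.sort(key=lambda t: (-t[0], t[1]))
    for new, (_, lab) in enumerate(keep, start=1):
        out[labels == lab] = new
    return out


def _split_balanced_branches(lk: np.ndarray, labels: np.ndarray,
                             min_module_size: int) -> np.ndarray:
    """Recursively split clusters at balanced subtree roots.

    Within each cluster, the merge node joining two branches that both
    contain >= ``min_module_size`` leaves marks a block boundary; the two
    branches become separate clusters and the rule recurses into them.
    """
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(lk)
    labels = labels.copy()
    next_label = labels.max() + 1

    def leaves(node) -> list[int]:
        return node.pre_order(lambda x: x.id)

    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            continue
        lv = leaves(node)
        if len({labels[i] for i in lv}) == 1 and \
                node.left.get_count() >= min_module_size and \
                node.right.get_count() >= min_module_size:
            for i in leaves(node.right):
                labels[i] = next_label
            next_label += 1
        stack.append(node.left)
        stack.append(node.right)
    return labels


def detect_modules(dissim: np.ndarray, gene_ids: list[str],
                   min_module_size: int = 10,
                   cut_height: float = 0.998) -> ModuleAssignment:
    """Cut the average-linkage tree of a TOM dissimilarity into modules.

    A static cut at ``cut_height`` defines coarse clusters; each cluster is
    then recursively split at its subtree root whenever both branches hold
    at least ``min_module_size`` genes.  Under average linkage, balanced
    branches arise at genuine block boundaries while homogeneous modules
    accrete genes one at a time, so the rule separates co-expression blocks
    that a single static height cannot resolve without introducing a new
    threshold.  Clusters smaller than ``min_module_size`` are relabeled
    module 0 (unassigned); the rest are renumbered 1..M by decreasing size.
    """
    n = dissim.shape[0]
    if n < 2:
        raise UsageError("detect_modules needs at least 2 genes")
    if len(gene_ids) != n:
        raise UsageError("gene_ids length does not match dissimilarity")
    d = np.asarray(dissim, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    lk = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(lk, t=cut_height, criterion="distance")
    raw = _split_balanced_branches(lk, raw, min_module_size)
    labels = _relabel_by_size(raw, min_module_size)
    assigned = int((labels != 0).sum())
    logger.info("detect_modules: %d modules over %d/%d genes (cut %.3g, min size %d)",
                labels.max(initial=0), assigned, n, cut_height, min_module_size)
    return ModuleAssignment(pd.Series(labels, index=pd.Index(gene_ids), dtype=int))


def module_eigengenes(x: ExpressionMatrix, assign: ModuleAssignment) -> EigengeneTable:
    """First-principal-component summary of each module.

    Genes are z-scored across samples; the eigengene is the leading right
    singular vector of the module's standardized submatrix, rescaled to unit
    sample variance and sign-fixed so it correlates non-negatively with the
    module's mean standardized expression.  ``variance_explained`` is
    sigma_1^2 / sum sigma^2.
    """
    cols: dict[str, np.ndarray] = {}
    var_exp: dict[int, float] = {}
    n_samples = x.shape[1]
    for m in assign.module_indices():
        genes = [g for g in assign.genes_in(m) if g in x.data.index]
        if not genes:
            raise ValidationError(f"module {m} has no genes present in the matrix")
        sub = x.data.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        ok = sd > 0
        if not ok.any():
            raise ValidationError(f"module {m} contains only zero-variance genes")
        if not ok.all():
            logger.warning("module %d: dropping %d zero-variance genes from eigengene",
                           m, int((~ok).sum()))
        z = (sub[ok] - sub[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        ref = z.mean(axis=0)
        align = float(eig @ (ref - ref.mean()))
        if align < 0 or (align == 0 and eig[0] < 0):
            eig = -eig
        eig = eig / eig.std(ddof=1)
        cols[f"ME{m}"] = eig
        var_exp[m] = float(s[0] ** 2 / (s ** 2).sum())
    data = pd.DataFrame(cols, index=pd.Index(x.sample_ids))
    if data.shape[1] == 0:
        data = pd.DataFrame(index=pd.Index(x.sample_ids))
    assert data.shape[0] == n_samples
    return EigengeneTable(data, var_exp)


def merge_close_modules(x: ExpressionMatrix, assign: ModuleAssignment,
                        me: EigengeneTable,
                        merge_height: float = 0.25) -> tuple[ModuleAssignment, EigengeneTable]:
    """Collapse modules whose eigengene dissimilarity 1 - cor falls strictly
    below ``merge_height``; recompute eigengenes and iterate to a fixed point.
    The module count never increases."""
    if not 0 < merge_height < 1:
        raise UsageError("merge_height must be in (0, 1)")
    current = assign
    table = me
    while True:
        idx = table.module_indices()
        if len(idx) < 2:
            break
        vals = table.data.to_numpy(dtype=float)
        cor = np.corrcoef(vals.T)
        d = 1.0 - cor
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        d = np.maximum(d, 0.0)
        lk = linkage(squareform(d, checks=False), method="average")
        # strict "< merge_height": cut just below the boundary
        groups = fcluster(lk, t=np.nextafter(merge_height, 0.0), criterion="distance")
        if len(set(groups)) == len(idx):
            break
        mapping: dict[int, int] = {}
        for g in sorted(set(groups)):
            members = [idx[i] for i in range(len(idx)) if groups[i] == g]
            for m in members:
                mapping[m] = members[0]
        merged = current.modules.map(lambda v: mapping.get(v, 0) if v != 0 else 0)
        sizes = merged[merged != 0].value_counts()
        order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
        relabel = {old: new for new, old in enumerate(order, start=1)}
        merged = merged.map(lambda v: relabel.get(v, 0))
        current = ModuleAssignment(merged.astype(int))
        logger.info("merge_close_modules: %d -> %d modules", len(idx), current.n_modules())
        table = module_eigengenes(x, current)
    return current, table


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def connectivity(a: AdjacencyMatrix, assign: ModuleAssignment,
                 x: ExpressionMatrix | None = None,
                 me: EigengeneTable | None = None) -> pd.DataFrame:
    """Per-gene kTotal, kWithin and module membership.

    kTotal is the row sum of the (zero-diagonal) adjacency; kWithin sums
    over same-module partners.  Module membership — the correlation of a
    gene's profile with its own module eigengene — needs ``x`` and ``me``
    and is NaN otherwise and for module-0 genes.
    """
    ids = a.node_ids
    labels = assign.modules.reindex(ids).fillna(0).astype(int).to_numpy()
    av = a.values
    k_total = av.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    same &= labels[:, None] != 0
    k_within = (av * same).sum(axis=1)
    mm = np.full(len(ids), np.nan)
    if x is not None and me is not None:
        for i, g in enumerate(ids):
            m = labels[i]
            col = f"ME{m}"
            if m == 0 or col not in me.data.columns or g not in x.data.index:
                continue
            prof = x.data.loc[g, me.sample_ids].to_numpy(dtype=float)
            if prof.std() == 0:
                continue
            mm[i] = np.corrcoef(prof, me.data[col].to_numpy())[0, 1]
    return pd.DataFrame({"module": labels, "kTotal": k_total,
                         "kWithin": k_within, "module_membership": mm},
                        index=pd.Index(ids))


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------

def build_modules(x: ExpressionMatrix, config: RunConfig | None = None
                  ) -> tuple[ModuleAssignment, EigengeneTable, AdjacencyMatrix]:
    """Full co-expression stage: bicor -> signed hybrid -> TOM -> modules ->
    eigengenes -> merge; returns the merged assignment (with connectivity
    stats attached), the eigengene table, and the adjacency."""
    config = config or RunConfig()
    cor = bicor_matrix(x)
    adj = signed_hybrid_adjacency(cor, config.soft_power)
    dissim = 1.0 - tom_similarity(adj)
    assign = detect_modules(dissim, cor.node_ids,
                            min_module_size=config.min_module_size,
                            cut_height=config.cut_height)
    if set(cor.node_ids) != set(x.gene_ids):
        # zero-variance genes excluded from the network -> module 0
        assign = ModuleAssignment(assign.modules.reindex(x.gene_ids).fillna(0).astype(int))
    me = module_eigengenes(x, assign)
    if assign.n_modules() >= 2:
        assign, me = merge_close_modules(x, assign, me, config.merge_height)
    stats = connectivity(adj, assign, x, me)
    assign.stats = stats
    return assign, me, adj
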