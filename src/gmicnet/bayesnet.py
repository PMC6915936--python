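"""Discrete Bayesian-network machinery: information-preserving
discretization, BDeu scoring, tabu structure search, bootstrap arc strength
and network averaging.

The causal layer of the pipeline.  Continuous eigengene/signature tables are
discretized by quantile pre-binning followed by greedy adjacent-level merges
that minimize the loss of total pairwise mutual information (Hartemink's
scheme).  Structures are scored with the Bayesian Dirichlet equivalent
uniform (BDeu) marginal likelihood and searched by tabu-augmented hill
climbing over arc additions, deletions and reversals.  Nonparametric
bootstrap replicates yield per-arc strength (edge frequency) and direction
(orientation frequency); the averaged network keeps arcs above a
data-driven significance threshold and is forced acyclic.
"""

from __future__ import annotations

import itertools
import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_io import UsageError, ValidationError

logger = logging.getLogger("gmicnet")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DiscreteTable:
    """observations x variables matrix of integer level indices."""

    variables: list[str]
    levels: list[int]
    data: np.ndarray  # (n, p) int

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(self.variables):
            raise ValidationError("discrete table shape mismatch")
        if len(self.levels) != len(self.variables):
            raise ValidationError("levels/variables mismatch")
        for j, r in enumerate(self.levels):
            col = self.data[:, j]
            if col.min(initial=0) < 0 or col.max(initial=0) >= r:
                raise ValidationError(
                    f"variable {self.variables[j]!r} has level index outside [0, {r})")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def resample(self, rng: np.random.Generator) -> "DiscreteTable":
        idx = rng.integers(0, self.n, self.n)
        return DiscreteTable(self.variables, list(self.levels), self.data[idx])


@dataclass
class Dag:
    """Directed acyclic graph over named nodes.

    ``arcs`` are ordered pairs; ``arc_info`` optionally carries
    (strength, direction) for arcs kept by network averaging.
    """

    nodes: list[str]
    arcs: set[tuple[str, str]] = field(default_factory=set)
    arc_info: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for u, v in self.arcs:
            if u == v:
                raise ValidationError(f"self-arc {u}->{v}")
            if u not in node_set or v not in node_set:
                raise ValidationError(f"arc endpoint missing from node set: {u}->{v}")
        if self.topological_order() is None:
            raise ValidationError("graph contains a cycle")

    def topological_order(self) -> list[str] | None:
        indeg = {n: 0 for n in self.nodes}
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for u, v in self.arcs:
            indeg[v] += 1
            children[u].append(v)
        ready = sorted(n for n, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for c in sorted(children[n]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
            ready.sort()
        return order if len(order) == len(self.nodes) else None

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.arcs if v == node))

    def to_networkx(self):
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g


@dataclass
class ArcStrengthTable:
    """Bootstrap edge frequency and orientation probability per ordered pair.

    ``strength`` is symmetric in the unordered pair; ``direction(i,j) +
    direction(j,i) = 1`` whenever the strength is positive.  One row per
    ordered pair with nonzero strength.
    """

    table: pd.DataFrame  # columns: from, to, strength, direction

    def __post_init__(self) -> None:
        t = self.table
        required = ["from", "to", "strength", "direction"]
        if list(t.columns[:4]) != required:
            raise ValidationError(f"arc strength table needs columns {required}")
        if len(t) == 0:
            return
        if t["strength"].min() < 0 or t["strength"].max() > 1:
            raise ValidationError("strength outside [0, 1]")
        if t["direction"].min() < 0 or t["direction"].max() > 1:
            raise ValidationError("direction outside [0, 1]")
        lut = {(r["from"], r["to"]): (r["strength"], r["direction"])
               for _, r in t.iterrows()}
        for (u, v), (s, d) in lut.items():
            if s <= 0:
                raise ValidationError("rows must have nonzero strength")
            s2, d2 = lut.get((v, u), (None, None))
            if s2 is None or abs(s - s2) > 1e-9 or abs(d + d2 - 1) > 1e-9:
                raise ValidationError(f"pair ({u}, {v}) violates symmetry/direction-sum")

    def __len__(self) -> int:
        return len(self.table)

    def strengths(self) -> np.ndarray:
        """Unordered-pair strengths (one entry per pair)."""
        seen = set()
        vals = []
        for _, r in self.table.iterrows():
            key = frozenset((r["from"], r["to"]))
            if key not in seen:
                seen.add(key)
                vals.append(float(r["strength"]))
        return np.array(vals)


# ---------------------------------------------------------------------------
# mutual information + Hartemink discretization
# ---------------------------------------------------------------------------

def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two integer-coded vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    ra, rb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * rb + b, minlength=ra * rb).astype(float).reshape(ra, rb)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])).sum())


def _quantile_bin(x: np.ndarray, ibreaks: int) -> np.ndarray:
    """Initial quantile binning into at most ``ibreaks`` occupied levels."""
    qs = np.quantile(x, np.linspace(0, 1, ibreaks + 1)[1:-1])
    levels = np.searchsorted(qs, x, side="left")
    # compress to consecutive occupied levels
    _, compressed = np.unique(levels, return_inverse=True)
    return compressed


def hartemink_discretize(table: pd.DataFrame, breaks: int = 3,
                         ibreaks: int = 20,
                         tie_tol: float | None = None,
                         return_trace: bool = False):
    """Information-preserving discretization of a numeric table.

    Every variable is quantile-binned into ``ibreaks`` levels, then adjacent
    levels are merged greedily — each step collapses the pair whose merge
    loses the least total pairwise mutual information against all other
    variables — until ``breaks`` levels remain.  Variables are processed in
    column order.

    The greedy step is exact by default: the chosen merge never loses more
    total mutual information than any alternative at that step.  A merge
    erases one bin boundary; ties are resolved by erasing the boundary whose
    cumulative position is farthest from the ideal quantile boundaries
    {i/breaks}, preserving quantile structure.  Setting ``tie_tol`` > 0
    additionally treats losses within that tolerance as ties, which pulls
    the binning toward balanced quantiles when the empirical mutual
    information is dominated by sampling noise (order (r-1)/(2n) per
    companion for independent variables).

    With ``return_trace`` the result is ``(table, trace)`` where each trace
    entry records one merge: (variable, chosen total MI after the merge, the
    totals of every alternative merge at that step) — so stepwise greedy
    optimality is directly assertable.
    """
    if table.shape[1] < 2:
        raise UsageError("Hartemink discretization needs >= 2 variables "
                         "(the merge criterion is mutual information with companions)")
    if not 2 <= breaks < ibreaks:
        raise UsageError("need 2 <= breaks < ibreaks")
    variables = [str(c) for c in table.columns]
    n = table.shape[0]
    cols: list[np.ndarray] = []
    for name in table.columns:
        x = table[name].to_numpy(dtype=float)
        distinct = np.unique(x).size
        if distinct < breaks:
            raise ValidationError(
                f"variable {name!r} has {distinct} distinct values; needs >= {breaks}")
        binned = _quantile_bin(x, min(ibreaks, distinct))
        if binned.max() + 1 < breaks:
            raise ValidationError(
                f"variable {name!r} yields fewer than {breaks} occupied initial levels")
        cols.append(binned)

    data = np.column_stack(cols)
    p = len(variables)

    ideal = np.array([i / breaks for i in range(1, breaks)])

    trace: list[tuple[str, float, list[float]]] = []
    for j in range(p):
        others = [k for k in range(p) if k != j]
        tol = tie_tol if tie_tol is not None else 0.0
        while data[:, j].max() + 1 > breaks:
            col = data[:, j]
            n_levels = col.max() + 1
            cum = np.cumsum(np.bincount(col)) / n  # boundary after level lo
            scored = []
            for lo in range(n_levels - 1):
                cand = np.where(col > lo, col - 1, col)
                total = sum(mutual_information(cand, data[:, k]) for k in others)
                boundary_badness = np.abs(ideal - cum[lo]).min()
                scored.append((total, boundary_badness, -lo, cand))
            best_total = max(s[0] for s in scored)
            tied = [s for s in scored if s[0] >= best_total - tol]
            chosen_total, _, _, winner = max(tied, key=lambda s: (s[1], s[2]))
            trace.append((variables[j], chosen_total, [s[0] for s in scored]))
            data[:, j] = winner
    result = DiscreteTable(variables, [breaks] * p, data.astype(np.int64))
    return (result, trace) if return_trace else result


# ---------------------------------------------------------------------------
# BDeu score
# ---------------------------------------------------------------------------

def _family_score(child: int, parents: tuple[int, ...], d: DiscreteTable,
                  iss: float) -> float:
    """BDeu log marginal likelihood of one node given its parent set."""
    r = d.levels[child]
    child_col = d.data[:, child]
    if parents:
        q = 1
        config = np.zeros(d.n, dtype=np.int64)
        for pidx in parents:
            config = config * d.levels[pidx] + d.data[:, pidx]
            q *= d.levels[pidx]
    else:
        q = 1
        config = np.zeros(d.n, dtype=np.int64)
    counts = np.bincount(config * r + child_col, minlength=q * r).astype(float)
    counts = counts.reshape(q, r)
    n_j = counts.sum(axis=1)
    a_jk = iss / (q * r)
    a_j = iss / q
    score = (gammaln(a_j) - gammaln(a_j + n_j)).sum()
    score += (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
    return float(score)


def bdeu_score(g: Dag, d: DiscreteTable, iss: float = 1.0) -> float:
    """BDeu (Bayesian Dirichlet equivalent uniform) network score.

    Sum over nodes of the family marginal likelihood with Dirichlet
    hyperparameters iss / (q_i r_i); likelihood-equivalent, so Markov
    equivalent DAGs score identically.
    """
    if iss <= 0:
        raise UsageError("iss must be > 0")
    index = {v: i for i, v in enumerate(d.variables)}
    missing = [n for n in g.nodes if n not in index]
    if missing:
        raise ValidationError(f"graph nodes absent from data: {missing}")
    total = 0.0
    for node in g.nodes:
        parents = tuple(index[p] for p in g.parents(node))
        total += _family_score(index[node], parents, d, iss)
    return total


# ---------------------------------------------------------------------------
# tabu structure search
# ---------------------------------------------------------------------------

class _SearchState:
    """Mutable DAG + cached family scores during search."""

    def __init__(self, d: DiscreteTable, iss: float):
        self.d = d
        self.iss = iss
        self.p = len(d.variables)
        self.parents: list[frozenset[int]] = [frozenset() for _ in range(self.p)]
        self.cache: dict[tuple[int, frozenset[int]], float] = {}
        self.family: list[float] = [self.score_family(j, frozenset()) for j in range(self.p)]

    def score_family(self, child: int, parents: frozenset[int]) -> float:
        key = (child, parents)
        if key not in self.cache:
            self.cache[key] = _family_score(child, tuple(sorted(parents)), self.d, self.iss)
        return self.cache[key]

    def total(self) -> float:
        return sum(self.family)

    def creates_cycle(self, frm: int, to: int) -> bool:
        """Would adding frm->to create a cycle? (path to->...->frm check)"""
        stack = [to]
        seen = {to}
        while stack:
            node = stack.pop()
            if node == frm:
                return True
            for child in range(self.p):
                if node in self.parents[child] and child not in seen:
                    seen.add(child)
                    stack.append(child)
        return False

    def arcs(self) -> set[tuple[int, int]]:
        return {(u, v) for v in range(self.p) for u in self.parents[v]}


def tabu_learn(d: DiscreteTable, iss: float = 1.0, tabu_len: int = 10,
               max_worsening: int = 10, max_iter: int | None = None,
               seed: int = 0) -> Dag:
    """BDeu-scored structure search: greedy hill climbing over arc
    additions, deletions and reversals with a tabu memory.

    When no move improves, the best non-tabu move is taken anyway (up to
    ``max_worsening`` consecutive worsening steps) to escape local optima;
    a tabu list of the last ``tabu_len`` inverse moves blocks immediate
    backtracking, with aspiration (a move beating the incumbent best is
    always allowed).  The best structure visited is returned.  Fully
    deterministic: moves are scanned in a fixed order, strict improvement
    required to switch, first-found tie kept; ``seed`` is accepted for
    interface uniformity and reproducibility bookkeeping.
    """
    if len(d.variables) < 2:
        raise UsageError("structure learning needs >= 2 variables")
    if d.n < 1:
        raise UsageError("structure learning needs >= 1 observation")
    if max_iter is None:
        max_iter = 10 * len(d.variables) ** 2
    if max_iter <= 0:
        raise UsageError("max_iter must be positive")
    _ = seed  # search is deterministic; parameter kept for provenance

    st = _SearchState(d, iss)
    p = st.p
    best_parents = [fs for fs in st.parents]
    best_score = st.total()
    current_score = best_score
    tabu: deque[tuple[str, int, int]] = deque(maxlen=tabu_len)
    worsening = 0

    for _ in range(max_iter):
        best_move = None
        best_delta = -np.inf
        for frm in range(p):
            for to in range(p):
                if frm == to:
                    continue
                if frm in st.parents[to]:
                    # delete frm->to
                    new_parents = st.parents[to] - {frm}
                    delta = st.score_family(to, new_parents) - st.family[to]
                    moves = [("del", frm, to, delta, (to, new_parents, None, None))]
                    # reverse frm->to (delete + add to->frm)
                    if not _reverse_creates_cycle(st, frm, to):
                        np_to = st.parents[to] - {frm}
                        np_frm = st.parents[frm] | {to}
                        rdelta = (st.score_family(to, np_to) - st.family[to]
                                  + st.score_family(frm, np_frm) - st.family[frm])
                        moves.append(("rev", frm, to, rdelta, (to, np_to, frm, np_frm)))
                else:
                    if to in st.parents[frm] or st.creates_cycle(frm, to):
                        continue
                    new_parents = st.parents[to] | {frm}
                    delta = st.score_family(to, new_parents) - st.family[to]
                    moves = [("add", frm, to, delta, (to, new_parents, None, None))]
                for op, a, b, delta, payload in moves:
                    if (op, a, b) in tabu and current_score + delta <= best_score + 1e-12:
                        continue  # tabu without aspiration
                    if delta > best_delta + 1e-12:
                        best_delta = delta
                        best_move = (op, a, b, delta, payload)
        if best_move is None:
            break
        op, a, b, delta, (to, np_to, frm2, np_frm) = best_move
        st.family[to] = st.score_family(to, np_to)
        st.parents[to] = np_to
        if frm2 is not None:
            st.family[frm2] = st.score_family(frm2, np_frm)
            st.parents[frm2] = np_frm
        current_score += delta
        tabu.append({"add": ("del", a, b), "del": ("add", a, b),
                     "rev": ("rev", b, a)}[op])
        if current_score > best_score + 1e-12:
            best_score = current_score
            best_parents = [fs for fs in st.parents]
            worsening = 0
        else:
            worsening += 1
            if worsening > max_worsening:
                break

    arcs = {(d.variables[u], d.variables[v])
            for v in range(p) for u in best_parents[v]}
    return Dag(list(d.variables), arcs)


def _reverse_creates_cycle(st: _SearchState, frm: int, to: int) -> bool:
    """Would reversing frm->to (to to->frm) create a cycle?

    Equivalent to: after removing frm->to, is there still a path frm->...->to?
    """
    saved = st.parents[to]
    st.parents[to] = saved - {frm}
    try:
        return st.creates_cycle(to, frm)
    finally:
        st.parents[to] = saved


# ---------------------------------------------------------------------------
# bootstrap arc strength
# ---------------------------------------------------------------------------

def boot_strength(d: DiscreteTable, replicates: int = 500, iss: float = 1.0,
                  tabu_len: int = 10, max_worsening: int = 10,
                  max_iter: int | None = None, seed: int = 0) -> ArcStrengthTable:
    """Nonparametric bootstrap arc strength.

    Replicate r resamples the rows with replacement using seed ``seed + r``
    (so partial runs are reproducible and parallelizable), learns a
    structure, and the table reports per unordered pair the fraction of
    replicates containing the edge (strength) and, given the edge, the
    fraction oriented each way (direction).
    """
    if replicates < 1:
        raise UsageError("replicates must be >= 1")
    variables = d.variables
    arc_counts: dict[tuple[str, str], int] = {}
    for r in range(replicates):
        rng = np.random.default_rng(seed + r)
        g = tabu_learn(d.resample(rng), iss=iss, tabu_len=tabu_len,
                       max_worsening=max_worsening, max_iter=max_iter)
        for arc in g.arcs:
            arc_counts[arc] = arc_counts.get(arc, 0) + 1
    rows = []
    for u, v in itertools.combinations(variables, 2):
        n_uv = arc_counts.get((u, v), 0)
        n_vu = arc_counts.get((v, u), 0)
        edge = n_uv + n_vu
        if edge == 0:
            continue
        strength = edge / replicates
        rows.append({"from": u, "to": v, "strength": strength,
                     "direction": n_uv / edge})
        rows.append({"from": v, "to": u, "strength": strength,
                     "direction": n_vu / edge})
    table = pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])
    return ArcStrengthTable(table)


# ---------------------------------------------------------------------------
# threshold estimation and network averaging
# ---------------------------------------------------------------------------

def estimate_strength_threshold(a: ArcStrengthTable) -> float:
    """Data-driven significance threshold for arc strengths.

    Picks t* minimizing the L1 distance between the empirical CDF of the
    unordered-pair strengths and the ideal two-point distribution
    concentrated on {0, 1} whose 0-mass equals the fraction of strengths
    below t.  Candidates are the observed strengths and points just above
    each; the smallest minimizer is returned.
    """
    if len(a) == 0:
        raise UsageError("cannot estimate a threshold from an empty table")
    s = np.sort(a.strengths())
    uniq = np.unique(s)
    candidates = np.unique(np.concatenate([uniq, np.minimum(uniq + 1e-9, 1.0)]))
    xs = np.unique(np.concatenate([[0.0], uniq, [1.0]]))
    widths = np.diff(xs)
    ecdf_left = np.searchsorted(s, xs[:-1], side="right") / s.size
    best_t, best_l1 = None, np.inf
    for t in candidates:
        c = np.searchsorted(s, t, side="left") / s.size  # fraction strictly below t
        l1 = float((np.abs(ecdf_left - c) * widths).sum())
        if l1 < best_l1 - 1e-12:
            best_l1, best_t = l1, float(t)
    return best_t


def averaged_network(a: ArcStrengthTable,
                     threshold: float | None = None) -> Dag:
    """Consensus DAG from an arc-strength table.

    Keeps unordered pairs with strength >= threshold (data-driven when None)
    and orients each by majority direction (> 0.5; exact ties keep the
    lexicographically smaller orientation, logged).  If the kept arcs are
    cyclic, the arc with the smallest strength x direction product lying on
    a cycle is removed (logged) until acyclic.
    """
    import networkx as nx

    nodes = sorted(set(a.table["from"]).union(a.table["to"])) if len(a) else []
    if len(a) == 0:
        return Dag(nodes)
    if threshold is None:
        threshold = estimate_strength_threshold(a)
        logger.info("averaged_network: data-driven threshold %.4g", threshold)
    kept: dict[tuple[str, str], tuple[float, float]] = {}
    seen_pairs: set[frozenset] = set()
    for _, r in a.table.iterrows():
        u, v, s, dirv = r["from"], r["to"], float(r["strength"]), float(r["direction"])
        pair = frozenset((u, v))
        if pair in seen_pairs or s < threshold:
            continue
        seen_pairs.add(pair)
        other = float(a.table.loc[(a.table["from"] == v) & (a.table["to"] == u),
                                  "direction"].iloc[0])
        if dirv > other:
            kept[(u, v)] = (s, dirv)
        elif other > dirv:
            kept[(v, u)] = (s, other)
        else:
            lo, hi = sorted((u, v))
            logger.info("averaged_network: direction tie for (%s, %s); keeping %s->%s",
                        u, v, lo, hi)
            kept[(lo, hi)] = (s, 0.5)

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(kept)
    while not nx.is_directed_acyclic_graph(g):
        # an arc lies on a cycle iff both endpoints share a nontrivial SCC
        scc_of: dict[str, int] = {}
        for i, comp in enumerate(nx.strongly_connected_components(g)):
            if len(comp) > 1:
                for node in comp:
                    scc_of[node] = i
        on_cycle = [(u, v) for (u, v) in g.edges
                    if u in scc_of and scc_of.get(v) == scc_of[u]]
        weakest = min(on_cycle, key=lambda e: (kept[e][0] * kept[e][1], e))
        logger.info("averaged_network: breaking cycle by dropping %s->%s "
                    "(strength x direction = %.4g)", weakest[0], weakest[1],
                    kept[weakest][0] * kept[weakest][1])
        g.remove_edge(*weakest)
        del kept[weakest]
    return Dag(nodes, set(kept), dict(kept))
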