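"""Gene Module-Immune Cell network assembly, module naming, enrichment
arithmetic and gene-influence ranking.

Module eigengenes and scaled cell-type signature scores are joined on
samples and fed through the discrete Bayesian-network stack; the averaged
DAG over module and signature nodes is the GMIC network.  Modules are named
by hypergeometric over-representation against an annotation gene-set
collection, and the most influential genes of selected modules are ranked by
betweenness centrality in a gene-level directed network built with the same
bootstrap machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .bayesnet import (ArcStrengthTable, Dag, averaged_network, boot_strength,
                       estimate_strength_threshold, hartemink_discretize)
from .coexpression import (AdjacencyMatrix, EigengeneTable, ModuleAssignment,
                           bicor_matrix, connectivity, signed_hybrid_adjacency)
from .data_io import (ExpressionMatrix, GeneSetCollection, RunConfig,
                      UsageError, ValidationError)
from .signatures import SignatureScores

logger = logging.getLogger("gmicnet")


class NetworkNode(NamedTuple):
    id: str
    kind: str  # "module" | "signature"
    label: str


@dataclass
class GmicNetwork:
    """Averaged directed acyclic graph over module and signature nodes."""

    nodes: list[NetworkNode]
    arcs: list[tuple[str, str, float, float]]  # from, to, strength, direction
    threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate node ids")
        labels = [n.label for n in self.nodes]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate node labels")
        id_set = set(ids)
        for u, v, _, _ in self.arcs:
            if u not in id_set or v not in id_set:
                raise ValidationError(f"arc endpoint missing: {u}->{v}")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("GMIC network must be acyclic")

    def arc_records(self) -> list[dict]:
        return [{"from": u, "to": v, "strength": s, "direction": d}
                for u, v, s, d in self.arcs]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id, kind=n.kind, label=n.label)
        for u, v, s, d in self.arcs:
            g.add_edge(u, v, strength=s, direction=d)
        return g

    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def arc_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, _, _ in self.arcs}


# ---------------------------------------------------------------------------
# table assembly and network learning
# ---------------------------------------------------------------------------

def assemble_gmic_table(me: EigengeneTable, s: SignatureScores,
                        rescale_after_join: bool = False) -> pd.DataFrame:
    """Inner-join eigengenes and scaled signature scores on sample id.

    Columns are module eigengenes (ME<idx>) followed by signatures.  The
    signature scores must already be centered/scaled; re-scaling after the
    join is off by default (and logged when requested).
    """
    if not s.scaled:
        raise ValidationError("signature scores must be scaled before assembly")
    shared = [sid for sid in me.sample_ids if sid in set(s.sample_ids)]
    if not shared:
        raise ValidationError("eigengene and signature tables share no samples")
    if len(shared) < 10:
        raise ValidationError(
            f"only {len(shared)} shared samples; need >= 10 for network learning")
    collisions = set(me.data.columns).intersection(s.data.columns)
    if collisions:
        raise ValidationError(f"column name collision: {sorted(collisions)}")
    joined = pd.concat([me.data.loc[shared], s.data.loc[shared]], axis=1)
    if rescale_after_join:
        logger.info("assemble_gmic_table: re-scaling all columns after join")
        joined = (joined - joined.mean()) / joined.std(ddof=1)
    return joined


def learn_gmic(table: pd.DataFrame, config: RunConfig | None = None,
               node_kinds: dict[str, str] | None = None,
               labels: dict[str, str] | None = None) -> tuple[GmicNetwork, ArcStrengthTable]:
    """Learn the GMIC network from a joined eigengene/signature table.

    Composition of Hartemink discretization, bootstrap arc-strength
    estimation and network averaging; node kinds default to "module" for
    ME-prefixed columns and "signature" otherwise.
    """
    config = config or RunConfig()
    disc = hartemink_discretize(table, breaks=config.breaks, ibreaks=config.ibreaks)
    strength = boot_strength(disc, replicates=config.bootstrap_replicates,
                             iss=config.iss, tabu_len=config.tabu_len,
                             max_worsening=config.max_worsening,
                             seed=config.rng_seed)
    threshold = config.arc_threshold
    if threshold is None and len(strength) > 0:
        threshold = estimate_strength_threshold(strength)
    dag = averaged_network(strength, threshold)
    kinds = node_kinds or {c: ("module" if str(c).startswith("ME") else "signature")
                           for c in table.columns}
    labels = labels or {}
    nodes = [NetworkNode(str(c), kinds.get(str(c), "signature"),
                         labels.get(str(c), str(c))) for c in table.columns]
    arcs = [(u, v, *dag.arc_info.get((u, v), (1.0, 1.0))) for u, v in sorted(dag.arcs)]
    net = GmicNetwork(nodes=nodes, arcs=arcs, threshold=threshold,
                      provenance={"config_hash": config.config_hash(),
                                  "seed": config.rng_seed,
                                  "replicates": config.bootstrap_replicates})
    return net, strength


# ---------------------------------------------------------------------------
# module naming by gene-set over-representation
# ---------------------------------------------------------------------------

# a few biochemical terms with conventional short symbols; initials otherwise
_TERM_ABBREV = {
    "transferrin": "Tf",
    "immunoglobulin": "Ig",
    "mitochondrial": "Mt",
    "ribosomal": "Rib",
    "interferon": "IFN",
}


def abbreviate_set_name(name: str, max_len: int = 6) -> str:
    """Deterministic short token for a gene-set name.

    Each word contributes its conventional symbol when one exists
    ("transferrin" -> "Tf") and its capitalized initial otherwise; the token
    is truncated to ``max_len`` characters.  "Transferrin transport" -> "TfT".
    """
    parts = []
    for word in name.split():
        key = word.lower().strip(",;:()")
        parts.append(_TERM_ABBREV.get(key, word[0].upper()))
    return "".join(parts)[:max_len] or "M"


def name_modules(assign: ModuleAssignment, annotation: GeneSetCollection,
                 universe: list[str] | None = None,
                 label_map: dict[int, str] | None = None) -> dict[int, str]:
    """Label each module by its most over-represented annotation set.

    The hypergeometric upper tail P(X >= k) is computed for every set
    (universe = all assigned genes by default); the winning set's
    abbreviation plus the module index gives the label ("TfT-40").  Ties
    break by smaller p then lexicographic set name; modules overlapping no
    set are labeled "M<index>".  ``label_map`` overrides individual modules.
    """
    label_map = label_map or {}
    if universe is None:
        universe = [g for g in assign.gene_ids if assign.modules[g] != 0]
    uni = set(universe)
    n_universe = len(uni)
    labels: dict[int, str] = {}
    if len(annotation) == 0:
        logger.warning("name_modules: empty annotation; using generic labels")
    for m in assign.module_indices():
        if m in label_map:
            labels[m] = f"{label_map[m]}-{m}"
            continue
        module_genes = set(assign.genes_in(m)) & uni
        n_drawn = len(module_genes)
        best: tuple[float, str] | None = None
        for set_name in sorted(annotation.names()):
            members = set(annotation.members(set_name)) & uni
            k = len(module_genes & members)
            if k == 0 or n_drawn == 0:
                continue
            p = float(hypergeom.sf(k - 1, n_universe, len(members), n_drawn))
            if best is None or (p, set_name) < best:
                best = (p, set_name)
        labels[m] = f"{abbreviate_set_name(best[1])}-{m}" if best else f"M{m}"
    return labels


def module_enrichment_report(assign: ModuleAssignment, annotation: GeneSetCollection,
                             universe: list[str] | None = None) -> pd.DataFrame:
    """Per module x set over-representation p-values with BH adjustment."""
    from statsmodels.stats.multitest import multipletests

    if universe is None:
        universe = [g for g in assign.gene_ids if assign.modules[g] != 0]
    uni = set(universe)
    rows = []
    for m in assign.module_indices():
        module_genes = set(assign.genes_in(m)) & uni
        for set_name in sorted(annotation.names()):
            members = set(annotation.members(set_name)) & uni
            k = len(module_genes & members)
            p = float(hypergeom.sf(k - 1, len(uni), len(members), len(module_genes))) \
                if module_genes and members else 1.0
            rows.append({"module": m, "set": set_name, "overlap": k, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def enrichment_fold(k: int, n: int, big_k: int, big_n: int) -> tuple[float, float]:
    """Fold enrichment (k/n) / (K/N) and the hypergeometric tail P(X >= k).

    Example from differential-expression arithmetic: 8 of 23 module genes
    versus 98 of 560 measured genes gives a fold of about 2.
    """
    if not (0 <= k <= n <= big_n and k <= big_k <= big_n):
        raise UsageError("require 0 <= k <= n <= N and k <= K <= N")
    if n == 0 or big_k == 0:
        raise UsageError("fold is undefined for n = 0 or K = 0")
    fold = (k / n) / (big_k / big_n)
    p = float(hypergeom.sf(k - 1, big_n, big_k, n))
    return fold, p


# ---------------------------------------------------------------------------
# gene-level influence
# ---------------------------------------------------------------------------

def betweenness(g: nx.DiGraph | Dag) -> dict[str, float]:
    """Unnormalized directed shortest-path betweenness centrality."""
    if isinstance(g, Dag):
        g = g.to_networkx()
    return nx.betweenness_centrality(g, normalized=False)


def gene_subnetwork(x: ExpressionMatrix, assign: ModuleAssignment,
                    module_ids: list[int], config: RunConfig | None = None,
                    gene_edge_threshold: float | None = None,
                    replicates: int | None = None,
                    adjacency: AdjacencyMatrix | None = None
                    ) -> tuple[pd.DataFrame, nx.DiGraph]:
    """Directed gene network and influence ranking for selected modules.

    The selected modules' genes are run through the same discretize ->
    bootstrap -> average stack used at module level; arcs with strength
    below ``gene_edge_threshold`` (default 0.04) are pruned.  Influence is
    descending betweenness centrality on the resulting directed graph, ties
    broken by kTotal from the co-expression adjacency.
    """
    config = config or RunConfig()
    if gene_edge_threshold is None:
        gene_edge_threshold = config.gene_edge_threshold
    if replicates is None:
        replicates = config.bootstrap_replicates
    genes: list[str] = []
    for m in module_ids:
        members = assign.genes_in(m)
        if not members:
            raise UsageError(f"module {m} does not exist or is empty")
        genes.extend(members)
    if len(genes) > config.gene_cap:
        raise UsageError(
            f"{len(genes)} genes selected, above the cap of {config.gene_cap}; "
            "run modules separately or raise gene_cap")
    table = x.data.loc[genes].T  # samples x genes
    disc = hartemink_discretize(table, breaks=config.breaks, ibreaks=config.ibreaks)
    strength = boot_strength(disc, replicates=replicates, iss=config.iss,
                             tabu_len=config.tabu_len,
                             max_worsening=config.max_worsening,
                             seed=config.rng_seed)
    dag = averaged_network(strength, gene_edge_threshold)
    g = dag.to_networkx()
    btw = betweenness(g)
    if adjacency is None:
        adjacency = signed_hybrid_adjacency(
            bicor_matrix(ExpressionMatrix(x.data.loc[genes])), config.soft_power)
    conn = connectivity(adjacency, assign)
    rows = []
    for gene in genes:
        rows.append({"gene": gene,
                     "betweenness": btw.get(gene, 0.0),
                     "kTotal": float(conn.loc[gene, "kTotal"]) if gene in conn.index else 0.0,
                     "module": int(assign.modules[gene])})
    table_out = (pd.DataFrame(rows)
                 .sort_values(["betweenness", "kTotal"], ascending=False,
                              kind="mergesort")
                 .reset_index(drop=True))
    table_out["influence_rank"] = np.arange(1, len(table_out) + 1)
    return table_out, g
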