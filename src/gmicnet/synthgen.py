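"""Synthetic expression data with known ground truth.

Latent module factors are wired in a random DAG and propagated by
linear-Gaussian structural equations; each module's genes load on its factor
with additive Gaussian noise, background genes are pure noise, and cell-type
abundances (noisy functions of designated factors) are added onto marker
genes.  The matrix is shifted to a nonnegative log2-like scale and emitted
together with the true module map, the true factor/abundance DAG and a GMT
of the marker sets — so module detection, signature scoring and network
learning each have a planted-recovery test with no external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bayesnet import Dag
from .data_io import (ExpressionMatrix, GeneSetCollection, UsageError,
                      write_expression, write_gmt)

logger = logging.getLogger("gmicnet")


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic cohort.

    Defaults emulate a bulk log2-scale expression cohort with six
    factor-driven modules of 50 genes, 200 unstructured background genes,
    300 biopsies, per-gene noise sd 1 and factor loadings U(0.6, 1.0); two
    cell types leave additive marker signals (20 markers each, carved from
    the background pool).  Because the full per-sample abundance is shared
    by a cell type's markers, each marker block is itself a genuine
    co-expression module; truth labels record it as one (module K + c).
    Factor-DAG weights are capped at 0.7 so DAG-adjacent factors correlate
    at |cor| = w / sqrt(1 + w^2) <= 0.57 — dependent enough for the network
    layer to detect, distinct enough that their modules do not fuse.
    """

    n_modules: int = 6
    genes_per_module: int = 50
    n_samples: int = 300
    loading_range: tuple[float, float] = (0.6, 1.0)
    noise_sd: float = 1.0
    background_genes: int = 200
    n_celltypes: int = 2
    markers_per_celltype: int = 20
    p_edge: float = 0.3
    weight_range: tuple[float, float] = (0.4, 0.7)
    celltype_effect: float = 0.7
    celltype_noise_sd: float = 0.8
    base_level: float = 8.0
    seed: int = 0


@dataclass
class SyntheticBundle:
    expression: ExpressionMatrix
    truth_modules: dict[str, int]
    truth_dag: Dag
    truth_weights: dict[tuple[str, str], float]
    signature_gmt: GeneSetCollection
    params: GeneratorParams = field(default_factory=GeneratorParams)

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"expression": str(out / "expression.tsv"),
                 "truth": str(out / "truth.json"),
                 "gmt": str(out / "signatures.gmt")}
        write_expression(self.expression, paths["expression"])
        write_gmt(self.signature_gmt, paths["gmt"])
        with open(paths["truth"], "w") as fh:
            json.dump({"modules": self.truth_modules,
                       "dag_nodes": self.truth_dag.nodes,
                       "dag_arcs": sorted(self.truth_dag.arcs),
                       "weights": {f"{u}->{v}": w
                                   for (u, v), w in self.truth_weights.items()}},
                      fh, indent=1)
        return paths


def generate_factor_dag(k: int, p_edge: float, weight_range: tuple[float, float],
                        seed: int = 0,
                        node_prefix: str = "F") -> tuple[Dag, dict[tuple[str, str], float]]:
    """Random weighted DAG: random topological order, Bernoulli(p_edge) arcs,
    weights uniform in ``weight_range`` with random sign."""
    if k < 1:
        raise UsageError("need at least one node")
    if not 0 <= p_edge <= 1:
        raise UsageError("p_edge must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [f"{node_prefix}{i + 1}" for i in range(k)]
    order = rng.permutation(k)
    arcs: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            if rng.random() < p_edge:
                u, v = nodes[order[i]], nodes[order[j]]
                arcs.add((u, v))
                w = rng.uniform(*weight_range) * (1 if rng.random() < 0.5 else -1)
                weights[(u, v)] = float(w)
    return Dag(nodes, arcs), weights


def _sample_factors(dag: Dag, weights: dict[tuple[str, str], float],
                    n_samples: int, rng: np.random.Generator) -> pd.DataFrame:
    """Linear-Gaussian structural equations along the DAG, unit noise."""
    order = dag.topological_order()
    values: dict[str, np.ndarray] = {}
    for node in order:
        x = rng.standard_normal(n_samples)
        for parent in dag.parents(node):
            x = x + weights[(parent, node)] * values[parent]
        values[node] = x
    return pd.DataFrame(values)[dag.nodes]


def simulate_dataset(params: GeneratorParams | None = None,
                     seed: int | None = None) -> SyntheticBundle:
    """Generate a full synthetic bundle under ``params`` (see class doc).

    Module gene g in module m: loading_g * factor_m + N(0, noise_sd^2).
    Cell-type abundance c: celltype_effect * factor_{d(c)} + N(0,
    celltype_noise_sd^2), added onto that type's marker genes.  All values
    are shifted by ``base_level`` and clipped at zero to mimic a nonnegative
    log2 scale.  Bit-reproducible for a fixed seed.
    """
    params = params or GeneratorParams()
    if seed is not None:
        params = GeneratorParams(**{**params.__dict__, "seed": seed})
    if params.genes_per_module < 2:
        raise UsageError("genes_per_module must be >= 2")
    if params.markers_per_celltype * params.n_celltypes > params.background_genes:
        raise UsageError("not enough background genes to carve marker sets from")
    rng = np.random.default_rng(params.seed)

    k = params.n_modules
    dag, weights = generate_factor_dag(k, params.p_edge, params.weight_range,
                                       seed=params.seed)
    n = params.n_samples
    factors = _sample_factors(dag, weights, n, rng)

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth_modules: dict[str, int] = {}
    for m in range(1, k + 1):
        f = factors[f"F{m}"].to_numpy()
        for g in range(params.genes_per_module):
            loading = rng.uniform(*params.loading_range)
            gene = f"M{m}G{g + 1}"
            gene_rows.append(loading * f + rng.normal(0, params.noise_sd, n))
            gene_ids.append(gene)
            truth_modules[gene] = m
    for b in range(params.background_genes):
        gene = f"BG{b + 1}"
        gene_rows.append(rng.normal(0, params.noise_sd, n))
        gene_ids.append(gene)
        truth_modules[gene] = 0

    # cell-type abundances driven by designated factors (round-robin)
    ct_nodes: list[str] = []
    ct_arcs: set[tuple[str, str]] = set()
    ct_weights: dict[tuple[str, str], float] = {}
    gmt_sets: dict[str, tuple[str, list[str]]] = {}
    expr = np.vstack(gene_rows)
    bg_offset = k * params.genes_per_module
    for c in range(params.n_celltypes):
        ct = f"CT{c + 1}"
        driver = f"F{(c % k) + 1}"
        # standardized driver keeps cor(abundance, factor) at
        # effect / sqrt(effect^2 + noise^2) regardless of the factor's
        # position in the DAG (downstream factors have variance > 1)
        fv = factors[driver].to_numpy()
        abundance = (params.celltype_effect * (fv - fv.mean()) / fv.std()
                     + rng.normal(0, params.celltype_noise_sd, n))
        lo = bg_offset + c * params.markers_per_celltype
        hi = lo + params.markers_per_celltype
        expr[lo:hi] += abundance[None, :]
        markers = gene_ids[lo:hi]
        # shared abundance makes marker blocks genuine co-expression modules
        for gene in markers:
            truth_modules[gene] = k + c + 1
        gmt_sets[ct] = (f"synthetic markers of {ct}", list(markers))
        ct_nodes.append(ct)
        ct_arcs.add((driver, ct))
        ct_weights[(driver, ct)] = params.celltype_effect

    expr = np.maximum(expr + params.base_level, 0.0)
    matrix = ExpressionMatrix(pd.DataFrame(
        expr, index=pd.Index(gene_ids),
        columns=pd.Index([f"S{j + 1}" for j in range(n)])))
    truth_dag = Dag(dag.nodes + ct_nodes, dag.arcs | ct_arcs)
    logger.info("simulate_dataset: %d genes x %d samples, %d factor arcs, "
                "%d cell types", len(gene_ids), n, len(dag.arcs), params.n_celltypes)
    return SyntheticBundle(expression=matrix, truth_modules=truth_modules,
                           truth_dag=truth_dag,
                           truth_weights={**weights, **ct_weights},
                           signature_gmt=GeneSetCollection(gmt_sets),
                           params=params)
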