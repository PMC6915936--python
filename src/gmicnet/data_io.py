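"""Readers, writers and run configuration for the pipeline's external formats.

Expression matrices are delimiter-separated text with genes in rows and a
sample header; values are assumed already normalized on a log2 scale.  Gene
sets travel in GMT (name TAB description TAB members...).  Networks are
exported as TSV edge lists, SIF, or a fixed JSON schema so runs are
machine-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gmicnet")


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class GmicError(Exception):
    """Base class for all errors raised by gmicnet."""


class ParseError(GmicError):
    """A file could not be parsed (malformed cell, short line, ...)."""


class ValidationError(GmicError):
    """Parsed input violates a domain invariant (duplicates, empties, ...)."""


class UsageError(GmicError):
    """An argument is outside its documented domain."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale abundance.

    ``data`` is a pandas DataFrame indexed by gene id with sample ids as
    columns.  Identifiers must be unique and every value finite; missing
    values are rejected rather than imputed because every downstream step
    (correlation, discretization) assumes complete data.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression matrix contains missing/non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_expression(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes-in-rows expression matrix from TSV/CSV text.

    The first row is the sample header and the first column holds gene ids.
    ``delimiter`` defaults to a sniff between tab and comma.  A non-numeric
    cell raises :class:`ParseError` naming its gene row and sample column.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "\t" if first.count("\t") >= first.count(",") else ","
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression matrix")
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            cell = raw.loc[gene, col]
            raise ParseError(
                f"{path}: non-numeric cell {cell!r} at gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric)


def write_expression(x: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    x.data.to_csv(path, sep=delimiter, index_label="gene")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, ordered unique members)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


def _dedup(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for it in items:
        if it and it not in seen:
            seen.add(it)
            out.append(it)
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name TAB description TAB members."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields; GMT needs >= 3")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = _dedup(fields[2:])
            if not members:
                raise ParseError(f"{path}: line {lineno} ({name!r}) has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with the published defaults.

    max_zero_fraction: genes with a zero fraction strictly above this are
        dropped (0.9 = "more than 90% zeros").
    soft_power: signed-hybrid adjacency exponent beta (default 5).
    min_module_size: smallest admissible co-expression module (default 10).
    merge_height: eigengene-dissimilarity height below which modules merge
        (default 0.25, i.e. eigengene correlation above 0.75).
    breaks / ibreaks: final / initial level counts for the
        information-preserving discretization (3 and 20).
    bootstrap_replicates: bootstrap resamples for arc strength (500).
    iss: imaginary sample size of the BDeu score (1).
    arc_threshold: strength cutoff for the averaged network; None means the
        data-driven L1 estimator.
    gene_edge_threshold: strength cutoff for gene-level subnetworks (0.04).
    """

    max_zero_fraction: float = 0.9
    soft_power: float = 5.0
    min_module_size: int = 10
    merge_height: float = 0.25
    breaks: int = 3
    ibreaks: int = 20
    bootstrap_replicates: int = 500
    iss: float = 1.0
    arc_threshold: float | None = None
    gene_edge_threshold: float = 0.04
    cut_height: float = 0.998
    signature_alpha: float = 0.25
    tabu_len: int = 10
    max_worsening: int = 10
    gene_cap: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.max_zero_fraction < 1:
            raise ValidationError("max_zero_fraction must be in (0, 1)")
        if self.soft_power < 1:
            raise ValidationError("soft_power must be >= 1")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if not 0 < self.merge_height < 1:
            raise ValidationError("merge_height must be in (0, 1)")
        if not 2 <= self.breaks < self.ibreaks:
            raise ValidationError("need 2 <= breaks < ibreaks")
        if self.bootstrap_replicates < 1:
            raise ValidationError("bootstrap_replicates must be >= 1")
        if self.iss <= 0:
            raise ValidationError("iss must be > 0")
        for name in ("arc_threshold", "gene_edge_threshold"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0 < self.cut_height <= 1:
            raise ValidationError("cut_height must be in (0, 1]")
        if not 0 < self.signature_alpha <= 1:
            raise ValidationError("signature_alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("edge_list_tsv", "sif", "json")
_SIF_RELATION = "directs"


def write_network(net, path: str | Path, format: str = "edge_list_tsv") -> None:
    """Write a GMIC network as a TSV edge list, SIF, or JSON.

    The edge list carries the header ``from\\tto\\tstrength\\tdirection``;
    SIF uses the relation token ``directs``; JSON follows the fixed schema
    ``{nodes: [{id, kind, label}], arcs: [{from, to, strength, direction}]}``.
    """
    if format not in NETWORK_FORMATS:
        raise UsageError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    path = Path(path)
    arcs = net.arc_records()
    if format == "edge_list_tsv":
        with open(path, "w") as fh:
            fh.write("from\tto\tstrength\tdirection\n")
            for a in arcs:
                fh.write(f"{a['from']}\t{a['to']}\t{a['strength']:.6f}\t{a['direction']:.6f}\n")
    elif format == "sif":
        with open(path, "w") as fh:
            for a in arcs:
                fh.write(f"{a['from']}\t{_SIF_RELATION}\t{a['to']}\n")
    else:
        payload = {
            "nodes": [{"id": n.id, "kind": n.kind, "label": n.label} for n in net.nodes],
            "arcs": [{"from": a["from"], "to": a["to"],
                      "strength": round(a["strength"], 6),
                      "direction": round(a["direction"], 6)} for a in arcs],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def read_network(path: str | Path, format: str = "edge_list_tsv"):
    """Read a network written by :func:`write_network` (edge list or JSON)."""
    from .gmic import GmicNetwork, NetworkNode

    if format not in ("edge_list_tsv", "json"):
        raise UsageError(f"cannot read format {format!r} (write-only or unknown)")
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        nodes = [NetworkNode(n["id"], n["kind"], n["label"]) for n in payload["nodes"]]
        arcs = [(a["from"], a["to"], float(a["strength"]), float(a["direction"]))
                for a in payload["arcs"]]
        return GmicNetwork(nodes=nodes, arcs=arcs)
    df = pd.read_csv(path, sep="\t", dtype={"from": str, "to": str})
    ids = sorted(set(df["from"]).union(df["to"]))
    nodes = [NetworkNode(i, "module", i) for i in ids]
    arcs = [(r["from"], r["to"], float(r["strength"]), float(r["direction"]))
            for _, r in df.iterrows()]
    return GmicNetwork(nodes=nodes, arcs=arcs)
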