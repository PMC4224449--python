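"""Readers and writers for the pipeline's plain-text formats.

All tables travel as UTF-8 TSV with a header row and the row identifier in
the first column; gene sets as GMT (name TAB description TAB members...);
networks as two-column edge lists or SIF.  Identifiers are opaque
case-sensitive strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .errors import ParseError

__all__ = [
    "read_matrix_tsv", "write_matrix_tsv",
    "read_gmt", "write_gmt",
    "read_edge_list", "write_edge_list",
]

log = logging.getLogger(__name__)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a rows x columns numeric table; strict about shape and ids.

    Raises ParseError with the offending line number on ragged rows,
    duplicate row ids or non-numeric cells.  Tolerates Windows line endings.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    ncol = len(header)
    if ncol < 2:
        raise ParseError(f"{path}:1: header must have an id column and data columns")
    ids, rows = [], []
    seen = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ParseError(f"{path}:{ln}: expected {ncol} fields, got {len(fields)}")
        rid = fields[0]
        if rid in seen:
            raise ParseError(f"{path}:{ln}: duplicate row id {rid!r}")
        seen.add(rid)
        try:
            rows.append(np.array(fields[1:], dtype=float))
        except ValueError:
            raise ParseError(f"{path}:{ln}: non-numeric cell") from None
        ids.append(rid)
    return pd.DataFrame(np.vstack(rows) if rows else
                        np.empty((0, ncol - 1)),
                        index=pd.Index(ids, name=header[0]),
                        columns=header[1:])


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix = matrix.copy()
    matrix.index.name = matrix.index.name or "id"
    matrix.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path) -> dict:
    """GMT collection: set name TAB description TAB member...

    Duplicate members within a set are collapsed with a warning; fewer than
    three fields or an empty member list is a parse error.
    """
    path = Path(path)
    collection = {}
    with open(path, "r", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs >= 3 tab-separated fields")
            name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            if not members:
                raise ParseError(f"{path}:{ln}: gene set {name!r} has no members")
            uniq = set(members)
            if len(uniq) < len(members):
                log.warning("%s:%d: %d duplicate members collapsed in %r",
                            path, ln, len(members) - len(uniq), name)
            collection[name] = {"description": desc, "members": uniq}
    return collection


def write_gmt(collection: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection):
            entry = collection[name]
            desc = entry.get("description", "") if isinstance(entry, dict) else ""
            members = entry["members"] if isinstance(entry, dict) else entry
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


def read_edge_list(path) -> nx.Graph:
    """Undirected simple graph from a 2-column TSV edge list or a .sif file.

    Files ending in ``.sif`` are parsed as node TAB relation TAB node(s);
    anything else as TSV whose first two columns are the endpoints (extra
    columns ignored).  Self-loops and duplicate (including reversed) edges
    are dropped with logged counts.
    """
    path = Path(path)
    sif = path.suffix.lower() == ".sif"
    g = nx.Graph()
    n_self, n_dup = 0, 0
    with open(path, "r", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if sif:
                if len(fields) == 1:
                    g.add_node(fields[0])
                    continue
                if len(fields) < 3:
                    raise ParseError(f"{path}:{ln}: SIF line needs node, relation, node")
                pairs = [(fields[0], t) for t in fields[2:]]
            else:
                if len(fields) < 2:
                    raise ParseError(f"{path}:{ln}: edge line needs two node columns")
                pairs = [(fields[0], fields[1])]
            for u, v in pairs:
                if u == v:
                    n_self += 1
                    continue
                if g.has_edge(u, v):
                    n_dup += 1
                    continue
                g.add_edge(u, v)
    if n_self or n_dup:
        log.info("%s: dropped %d self-loops, %d duplicate edges", path, n_self, n_dup)
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    """Headerless two-column TSV, one undirected edge per line, sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted((min(u, v), max(u, v)) for u, v in graph.edges):
            fh.write(f"{u}\t{v}\n")
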