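"""Thresholded bipartite lncRNA-mRNA Pearson co-expression network.

Every deregulated lncRNA is correlated with every deregulated mRNA across
the pooled samples of one timepoint (both groups; within-group selectable)
on log2 intensities. Edges are kept under the strict inequalities used in
the source analysis — |r| > 0.995 AND p < 0.05 — in contrast to the
inclusive differential-expression thresholds. The p-value is the classical
t-transform test of the Pearson coefficient. Hubs are lncRNA nodes ranked
by degree; ties at the cut are broken lexicographically and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .study import ExpressionStudy

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["lnc", "mrna", "r", "p", "n", "sign"]


@dataclass
class CoexpressionNetwork:
    """Bipartite edge list plus node table with degrees.

    ``edges``: one row per retained lncRNA-mRNA pair (r, p, n, sign);
    ``nodes``: one row per tested transcript with role (lncRNA/mRNA),
    regulation direction when known, and degree. There are never
    lnc-lnc or mrna-mrna edges.
    """

    edges: pd.DataFrame
    nodes: pd.DataFrame
    r_threshold: float = 0.995
    p_threshold: float = 0.05

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return int(self.nodes.loc[node, "degree"])

    def lnc_nodes(self) -> pd.DataFrame:
        return self.nodes[self.nodes["role"] == "lncRNA"]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for nid, row in self.nodes.iterrows():
            g.add_node(nid, role=row["role"], regulation=row["regulation"],
                       degree=int(row["degree"]))
        for _, e in self.edges.iterrows():
            g.add_edge(e["lnc"], e["mrna"], r=float(e["r"]), p=float(e["p"]),
                       n=int(e["n"]), sign=e["sign"])
        return g


@dataclass
class HubRanking:
    """Top-k lncRNAs by connection count."""

    hubs: list[str]
    degrees: dict[str, int]
    tied_at_k: bool = False
    shortfall: bool = False


# ---------------------------------------------------------------------------
# correlation primitives

def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need n >= 3 samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero-variance vector: correlation undefined")
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.clip(xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc)),
                         -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    if n < 3:
        raise ValueError("need n >= 3 samples")
    if np.isnan(r):
        return float("nan")
    if abs(r) >= 1:
        logger.info("|r| = 1: p set to 0 by convention")
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# network construction

def build_network(de_lnc_ids, de_mrna_ids, study: ExpressionStudy,
                  timepoint: str | None = None,
                  r_threshold: float = 0.995, p_threshold: float = 0.05,
                  group: str | None = None,
                  direction: pd.Series | None = None) -> CoexpressionNetwork:
    """All lnc x mrna Pearson pairs, strictly thresholded.

    Samples default to the pooled groups of ``timepoint`` (all samples if
    None); set ``group`` to correlate within one group only. ``direction``
    optionally annotates nodes with their regulation (up/down).
    """
    de_lnc_ids, de_mrna_ids = list(de_lnc_ids), list(de_mrna_ids)
    if not de_lnc_ids or not de_mrna_ids:
        logger.warning("empty deregulated set: returning empty network")
        return _assemble(pd.DataFrame(columns=EDGE_COLUMNS), de_lnc_ids,
                         de_mrna_ids, direction, r_threshold, p_threshold)
    log2 = study.to_log2().intensities
    missing = (set(de_lnc_ids) | set(de_mrna_ids)) - set(log2.index)
    if missing:
        raise KeyError(f"ids absent from study: {sorted(missing)[:10]}")
    if timepoint is None:
        cols = list(log2.columns)
    else:
        cols = study.samples_for(timepoint, group)
    n = len(cols)
    if n < 3:
        raise ValueError("need >= 3 samples to correlate")

    A = log2.loc[de_lnc_ids, cols].to_numpy(dtype=float)
    B = log2.loc[de_mrna_ids, cols].to_numpy(dtype=float)

    def _standardise(M):
        Z = M - M.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(Z, axis=1)
        flat = norm == 0
        norm[flat] = 1.0
        return Z / norm[:, None], flat

    Za, flat_a = _standardise(A)
    Zb, flat_b = _standardise(B)
    n_flat = int(flat_a.sum() + flat_b.sum())
    if n_flat:
        logger.warning("%d zero-variance transcripts skipped", n_flat)
    R = np.clip(Za @ Zb.T, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt((n - 2) / (1.0 - R * R))
    P = 2.0 * stats.t.sf(np.abs(T), n - 2)
    P[np.abs(R) >= 1.0] = 0.0
    keep = (np.abs(R) > r_threshold) & (P < p_threshold)
    keep[flat_a, :] = False
    keep[:, flat_b] = False
    ii, jj = np.nonzero(keep)
    edges = pd.DataFrame({
        "lnc": [de_lnc_ids[i] for i in ii],
        "mrna": [de_mrna_ids[j] for j in jj],
        "r": R[ii, jj],
        "p": P[ii, jj],
        "n": n,
        "sign": np.where(R[ii, jj] > 0, "positive", "negative"),
    }, columns=EDGE_COLUMNS)
    return _assemble(edges, de_lnc_ids, de_mrna_ids, direction,
                     r_threshold, p_threshold)


def _assemble(edges, lnc_ids, mrna_ids, direction, r_thr, p_thr):
    deg_l = edges["lnc"].value_counts() if len(edges) else pd.Series(dtype=int)
    deg_m = edges["mrna"].value_counts() if len(edges) else pd.Series(dtype=int)
    nodes = pd.DataFrame({
        "role": ["lncRNA"] * len(lnc_ids) + ["mRNA"] * len(mrna_ids),
    }, index=pd.Index(list(lnc_ids) + list(mrna_ids), name="id"))
    degree = pd.concat([deg_l.reindex(lnc_ids, fill_value=0),
                        deg_m.reindex(mrna_ids, fill_value=0)])
    nodes["degree"] = degree.astype(int).to_numpy()
    if direction is not None:
        nodes["regulation"] = direction.reindex(nodes.index).fillna("unknown")
    else:
        nodes["regulation"] = "unknown"
    return CoexpressionNetwork(edges, nodes, r_thr, p_thr)


# ---------------------------------------------------------------------------
# hubs

def rank_hubs(network: CoexpressionNetwork, k: int = 5) -> HubRanking:
    """lncRNA nodes with the most connections, degree-descending.

    Only nodes with degree >= 1 count; ties are ordered lexicographically
    and a tie crossing the k-th rank is reported, never silently dropped.
    If fewer than k connected lncRNAs exist, all are returned with the
    shortfall flagged.
    """
    lnc = network.lnc_nodes()
    lnc = lnc[lnc["degree"] >= 1]
    ranked = sorted(lnc.index, key=lambda i: (-lnc.loc[i, "degree"], i))
    degrees = {i: int(lnc.loc[i, "degree"]) for i in ranked}
    if len(ranked) < k:
        logger.warning("only %d connected lncRNA nodes for top-%d",
                       len(ranked), k)
        return HubRanking(ranked, degrees, tied_at_k=False, shortfall=True)
    top = ranked[:k]
    tied = (len(ranked) > k and
            degrees[ranked[k]] == degrees[ranked[k - 1]])
    return HubRanking(top, {i: degrees[i] for i in top}, tied_at_k=tied)


def extract_subnetwork(network: CoexpressionNetwork,
                       hubs) -> tuple[CoexpressionNetwork, int]:
    """Edges incident to the hubs, plus the distinct-mRNA partner count."""
    hubs = list(hubs)
    lnc_nodes = set(network.lnc_nodes().index)
    unknown = [h for h in hubs if h not in lnc_nodes]
    if unknown:
        raise KeyError(f"unknown hub id(s): {unknown}")
    edges = network.edges[network.edges["lnc"].isin(hubs)].reset_index(drop=True)
    partners = sorted(edges["mrna"].unique())
    nodes = network.nodes.loc[hubs + partners].copy()
    deg_l = edges["lnc"].value_counts()
    deg_m = edges["mrna"].value_counts()
    nodes["degree"] = [int(deg_l.get(i, 0) + deg_m.get(i, 0))
                       for i in nodes.index]
    sub = CoexpressionNetwork(edges, nodes, network.r_threshold,
                              network.p_threshold)
    return sub, len(partners)


# ---------------------------------------------------------------------------
# export / import (Cytoscape-compatible)

def export_network(network: CoexpressionNetwork, path: str | Path,
                   fmt: str = "tsv") -> None:
    """Write as edge TSV, SIF (interactions pos/neg) or GraphML."""
    path = Path(path)
    if fmt == "tsv":
        network.edges.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for _, e in network.edges.iterrows():
                kind = "pos" if e["sign"] == "positive" else "neg"
                fh.write(f"{e['lnc']}\t{kind}\t{e['mrna']}\n")
    elif fmt == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path: str | Path, fmt: str = "tsv",
                 r_threshold: float = 0.995,
                 p_threshold: float = 0.05) -> CoexpressionNetwork:
    """Read a network written by :func:`export_network` (tsv or graphml)."""
    path = Path(path)
    if fmt == "tsv":
        edges = pd.read_csv(path, sep="\t")
        if edges.empty:
            edges = pd.DataFrame(columns=EDGE_COLUMNS)
        return _assemble(edges, list(pd.unique(edges["lnc"])),
                         list(pd.unique(edges["mrna"])), None,
                         r_threshold, p_threshold)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        rows, direction = [], {}
        lnc_ids, mrna_ids = [], []
        for nid, attrs in g.nodes(data=True):
            (lnc_ids if attrs.get("role") == "lncRNA" else mrna_ids).append(nid)
            direction[nid] = attrs.get("regulation", "unknown")
        lnc_set = set(lnc_ids)
        for u, v, attrs in g.edges(data=True):
            lnc, mrna = (u, v) if u in lnc_set else (v, u)
            rows.append((lnc, mrna, attrs["r"], attrs["p"],
                         attrs.get("n", 0), attrs["sign"]))
        edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        return _assemble(edges, sorted(lnc_ids), sorted(mrna_ids),
                         pd.Series(direction), r_threshold, p_threshold)
    raise ValueError(f"unknown format {fmt!r}")
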