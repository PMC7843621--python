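"""Gene-set enrichment with Cohen's-kappa functional grouping.

Enrichment of a query gene list (here: the mRNA partners of hub lncRNAs)
against GO/pathway catalogs uses the one-sided hypergeometric upper tail
(Fisher exact), conditioned on a measured-gene background. BH correction
is applied within each namespace separately, since terms are reported per
GO category. Significant terms are then grouped by Cohen's kappa of their
binary gene-membership vectors over the background: a term graph links
pairs with kappa above the threshold (0.03 in the source analysis) and
groups are its connected components, each led by its most significant
term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import CoexpressionNetwork
from .diffexpr import adjust_bh
from .genesets import GeneSetCatalog, NAMESPACES


@dataclass
class EnrichmentResult:
    """Per-term enrichment statistics.

    ``table`` is indexed by term id with columns ``namespace, term_size,
    overlap, p_raw, p_adj, gene_proportion, significant``; term_size and
    overlap are counted inside the background universe.
    """

    table: pd.DataFrame
    query_size: int
    background_size: int
    p_max: float = 0.05

    def significant_terms(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


@dataclass
class KappaGrouping:
    """Kappa-linked groups of significant terms.

    ``groups`` is ordered by leading-term significance; each entry carries
    the member terms and the leading term (smallest raw p; ties resolved
    toward the larger then lexicographically first term).
    """

    kappa_matrix: pd.DataFrame
    groups: list[dict]
    threshold: float


# ---------------------------------------------------------------------------
# primitives

def hypergeom_enrich(query, term, background) -> float:
    """Upper-tail hypergeometric P(X >= |query & term|).

    Drawing |query| genes from a |background| universe containing |term|
    term members.
    """
    query, term, background = set(query), set(term), set(background)
    if not background:
        raise ValueError("background must be non-empty")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    if not term <= background:
        raise ValueError("term genes must be a subset of the background")
    k = len(query & term)
    return float(stats.hypergeom.sf(k - 1, len(background), len(term),
                                    len(query)))


def kappa(term_a, term_b, background) -> float:
    """Cohen's kappa of two membership vectors over the background.

    kappa = (P_o - P_e) / (1 - P_e) from the 2x2 co-membership table;
    identical sets give 1 by definition (covers the degenerate P_e = 1
    case).
    """
    a, b, bg = set(term_a), set(term_b), set(background)
    if not (a | b) <= bg:
        raise ValueError("background smaller than the union of the two terms")
    if a == b:
        return 1.0
    n = len(bg)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    po = (n11 + n00) / n
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (n * n)
    return float((po - pe) / (1.0 - pe))


# ---------------------------------------------------------------------------
# catalog-wide enrichment

def enrich_all(query, catalog: GeneSetCatalog, background,
               p_max: float = 0.05) -> EnrichmentResult:
    """Hypergeometric enrichment of every term, BH within each namespace."""
    query, background = set(query), set(background)
    if not query:
        raise ValueError("empty query gene list")
    if not catalog.sets:
        raise ValueError("empty gene-set catalog")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    M, N = len(background), len(query)
    rows = []
    for term, members in catalog.sets.items():
        members = members & background
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), N))
        rows.append((term, catalog.namespaces[term], len(members), k, p))
    table = pd.DataFrame(rows, columns=["term", "namespace", "term_size",
                                        "overlap", "p_raw"]).set_index("term")
    table["p_adj"] = np.nan
    for ns in NAMESPACES:
        mask = table["namespace"] == ns
        if mask.any():
            table.loc[mask, "p_adj"] = adjust_bh(
                table.loc[mask, "p_raw"].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        table["gene_proportion"] = np.where(
            table["term_size"] > 0, table["overlap"] / table["term_size"], 0.0)
    table["significant"] = table["p_adj"] <= p_max
    return EnrichmentResult(table, N, M, p_max)


# ---------------------------------------------------------------------------
# kappa grouping

def group_terms(enrichment: EnrichmentResult, catalog: GeneSetCatalog,
                background, kappa_threshold: float = 0.03) -> KappaGrouping:
    """Connected components of the kappa > threshold term graph.

    Input term order never affects the result: terms are pre-sorted, and
    the leading term of each group is the smallest raw p (tie -> larger
    term, then lexicographic). Groups are ordered by leading-term
    significance. Singleton groups are kept.
    """
    terms = sorted(enrichment.significant_terms())
    if not terms:
        raise ValueError("no significant terms to group")
    background = set(background)
    members = {t: set(catalog.sets[t]) & background for t in terms}
    K = pd.DataFrame(np.eye(len(terms)), index=terms, columns=terms)
    g = nx.Graph()
    g.add_nodes_from(terms)
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            kv = kappa(members[a], members[b], background)
            K.loc[a, b] = K.loc[b, a] = kv
            if kv > kappa_threshold:
                g.add_edge(a, b)
    tab = enrichment.table
    groups = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        lead = min(comp, key=lambda t: (tab.loc[t, "p_raw"],
                                        -tab.loc[t, "term_size"], t))
        groups.append({"leading_term": lead,
                       "leading_p": float(tab.loc[lead, "p_raw"]),
                       "terms": comp})
    groups.sort(key=lambda grp: (grp["leading_p"], grp["leading_term"]))
    return KappaGrouping(K, groups, kappa_threshold)


# ---------------------------------------------------------------------------
# hub profiles

@dataclass
class HubProfile:
    """Significant terms enriched in each hub's own mRNA partner set."""

    table: pd.DataFrame  # columns: hub, term, namespace, p_raw, p_adj
    empty_hubs: list[str]


def hub_go_profile(subnetwork: CoexpressionNetwork, catalog: GeneSetCatalog,
                   background, p_max: float = 0.05) -> HubProfile:
    """Per-hub enrichment over that hub's partner mRNAs.

    Hubs without partners (or whose partners all fall outside the
    background) yield no rows and are listed in ``empty_hubs``.
    """
    background = set(background)
    rows, empty = [], []
    for hub in subnetwork.lnc_nodes().index:
        partners = set(subnetwork.edges.loc[subnetwork.edges["lnc"] == hub,
                                            "mrna"]) & background
        if not partners:
            empty.append(hub)
            continue
        res = enrich_all(partners, catalog, background, p_max=p_max)
        sig = res.table[res.table["significant"]]
        for term, r in sig.iterrows():
            rows.append((hub, term, r["namespace"], r["p_raw"], r["p_adj"]))
    table = pd.DataFrame(rows, columns=["hub", "term", "namespace",
                                        "p_raw", "p_adj"])
    return HubProfile(table, empty)
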