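"""Positional classification of lncRNAs and chromosomal DE summaries.

A lncRNA is assigned exactly one of six classes from its position relative
to the coding genes, evaluated against every gene on its chromosome and
resolved by a fixed most-specific-first precedence:

1. ``exon sense overlapping``  — overlaps >=1 bp of a coding exon, same strand
2. ``intron sense overlapping``— wholly inside one intron, same strand
3. ``intronic antisense``      — wholly inside one intron, opposite strand
4. ``natural antisense``       — overlaps the gene body, opposite strand,
                                 and is not intron-contained (rule 3)
5. ``bidirectional``           — no overlap with the gene, opposite strand,
                                 TSS within ``bidirectional_window`` bp of
                                 the gene TSS
6. ``intergenic``              — none of the above, for any gene

"Wholly inside an intron" means the full lncRNA interval lies within a
single intron; a same-strand transcript that straddles an exon boundary
touches exon bp and therefore falls to rule 1. With several candidate
genes the highest-precedence (lowest-numbered) label wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import percent
from .catalog import TranscriptCatalog

CLASS_LABELS = (
    "exon sense overlapping",
    "intron sense overlapping",
    "intronic antisense",
    "natural antisense",
    "bidirectional",
    "intergenic",
)


@dataclass
class ChromosomeSummary:
    """Per-chromosome up/down counts of deregulated transcripts.

    ``table`` has one row per chromosome with ``n_up, n_down, pct_up,
    pct_down``; shares are percentages of the study-wide up and down
    totals, shown to one decimal (round half away from zero). ``argmax``
    is the chromosome carrying the most deregulated transcripts overall.
    """

    table: pd.DataFrame
    total_up: int
    total_down: int
    argmax: str


def classify_lncrna(lnc, catalog: TranscriptCatalog,
                    bidirectional_window: int = 1000) -> str:
    """Class label for a single lncRNA (mapping-style with chrom/start/end/strand)."""
    labels = classify_all(
        pd.DataFrame([{k: lnc[k] for k in ("chrom", "start", "end", "strand")}],
                     index=["__query__"]),
        catalog, bidirectional_window)
    return labels.iloc[0]


def classify_all(lncs: pd.DataFrame, catalog: TranscriptCatalog,
                 bidirectional_window: int = 1000) -> pd.Series:
    """Vectorised classification of many lncRNAs against the gene models.

    ``lncs`` needs columns chrom/start/end/strand; returns a Series of
    labels aligned to its index. Labels never depend on gene input order
    (precedence is a minimum over genes).
    """
    known = catalog.chromosomes
    genes = catalog.genes
    introns = catalog.introns()
    exons = catalog.exons.merge(
        genes[["chrom", "strand"]], left_on="gene_id", right_index=True)
    introns = introns.merge(
        genes[["chrom", "strand"]], left_on="gene_id", right_index=True)
    tss = catalog.gene_tss()

    unknown = set(map(str, lncs["chrom"])) - known
    if unknown:
        raise ValueError(f"unknown chromosome label(s) {sorted(unknown)[:5]}")
    if (lncs["start"] >= lncs["end"]).any():
        bad = lncs.index[lncs["start"] >= lncs["end"]]
        raise ValueError(f"zero-length interval(s) for {list(bad[:5])}")

    best = pd.Series(6, index=lncs.index, dtype=int)
    for chrom, sub in lncs.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        ls = sub["start"].to_numpy()[:, None]
        le = sub["end"].to_numpy()[:, None]
        lstrand = sub["strand"].to_numpy()[:, None]
        rank = np.full(len(sub), 6, dtype=int)

        if len(g):
            gs = g["start"].to_numpy()[None, :]
            ge = g["end"].to_numpy()[None, :]
            gstrand = g["strand"].to_numpy()[None, :]
            gt = tss.loc[g.index].to_numpy()[None, :]
            same = lstrand == gstrand
            overlap = (ls < ge) & (gs < le)
            ltss = np.where(sub["strand"].to_numpy() == "+",
                            sub["start"].to_numpy(),
                            sub["end"].to_numpy())[:, None]
            near = np.abs(ltss - gt) <= bidirectional_window
            bidir = (~overlap) & (~same) & near
            antisense_body = overlap & ~same

            ex = exons[exons["chrom"] == chrom]
            if len(ex):
                es = ex["start"].to_numpy()[None, :]
                ee = ex["end"].to_numpy()[None, :]
                estrand = ex["strand"].to_numpy()[None, :]
                exon_sense = (ls < ee) & (es < le) & (lstrand == estrand)
                rank = np.where(exon_sense.any(axis=1), 1, rank)

            inr = introns[introns["chrom"] == chrom]
            contained_any = np.zeros(len(sub), dtype=bool)
            if len(inr):
                istart = inr["start"].to_numpy()[None, :]
                iend = inr["end"].to_numpy()[None, :]
                istrand = inr["strand"].to_numpy()[None, :]
                contained = (istart <= ls) & (le <= iend)
                sense_intron = (contained & (lstrand == istrand)).any(axis=1)
                anti_intron = (contained & (lstrand != istrand)).any(axis=1)
                contained_any = contained.any(axis=1)
                rank = np.minimum(rank, np.where(sense_intron, 2, 6))
                rank = np.minimum(rank, np.where(anti_intron, 3, 6))
            # natural antisense: gene-body overlap on the opposite strand
            # that is not an intron containment of that same transcript
            nat = antisense_body.any(axis=1) & ~contained_any
            rank = np.minimum(rank, np.where(nat, 4, 6))
            rank = np.minimum(rank, np.where(bidir.any(axis=1), 5, 6))
        best.loc[sub.index] = rank
    return best.map(lambda r: CLASS_LABELS[r - 1]).rename("positional_class")


def class_distribution(labels: pd.Series | list[str],
                       decimals: int = 0) -> pd.Series:
    """Percentage of lncRNAs per positional class.

    ``decimals=0`` gives the integer-percent display used in the source
    pie-chart style ("40% intergenic"); values sum to 100 up to rounding.
    """
    labels = pd.Series(list(labels))
    if labels.empty:
        raise ValueError("no labels to summarise")
    counts = labels.value_counts()
    total = int(counts.sum())
    out = counts.map(lambda c: percent(c, total, decimals))
    return out.reindex([c for c in CLASS_LABELS if c in out.index])


def chromosome_distribution(de, catalog: TranscriptCatalog,
                            biotype: str | None = None) -> ChromosomeSummary:
    """Per-chromosome up/down counts and shares for deregulated transcripts.

    Shares are against the total up-regulated and total down-regulated
    counts respectively (13 up of 92 on one chromosome -> 14.1%).
    """
    tab = de.table
    if biotype is not None:
        tab = tab[tab["biotype"] == biotype]
    dereg = tab[tab["deregulated"]]
    missing = dereg.index.difference(catalog.transcripts.index)
    if len(missing):
        raise KeyError(
            f"deregulated transcripts absent from catalog: {list(missing[:10])}")
    chrom = catalog.transcripts.loc[dereg.index, "chrom"]
    up = chrom[dereg["direction"] == "up"].value_counts()
    down = chrom[dereg["direction"] == "down"].value_counts()
    chroms = sorted(set(up.index) | set(down.index), key=_chrom_key)
    total_up, total_down = int(up.sum()), int(down.sum())
    table = pd.DataFrame({
        "n_up": up.reindex(chroms, fill_value=0).astype(int),
        "n_down": down.reindex(chroms, fill_value=0).astype(int),
    })
    table["pct_up"] = [percent(n, total_up) for n in table["n_up"]]
    table["pct_down"] = [percent(n, total_down) for n in table["n_down"]]
    table.index.name = "chrom"
    argmax = "" if table.empty else (table["n_up"] + table["n_down"]).idxmax()
    return ChromosomeSummary(table, total_up, total_down, str(argmax))


def _chrom_key(label: str):
    return (0, int(label)) if str(label).isdigit() else (1, str(label))
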