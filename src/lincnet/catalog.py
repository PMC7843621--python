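"""Genomic annotation of transcripts and coding-gene models.

Coordinates are 0-based half-open throughout (BED convention). The catalog
carries two layers: a flat per-transcript table (lncRNAs and mRNAs alike,
with chromosome / strand / interval / biotype) and, for the coding genes,
exon structure from which introns and transcription start sites are
derived. The TSS of a gene is its ``start`` on the + strand and its ``end``
on the - strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .study import LNCRNA, MRNA


@dataclass
class TranscriptCatalog:
    """Per-transcript annotation plus coding-gene exon models.

    Parameters
    ----------
    transcripts
        DataFrame indexed by transcript id with columns
        ``chrom, start, end, strand, biotype``.
    genes
        DataFrame indexed by gene id with columns ``chrom, start, end,
        strand`` (the coding genes; for array data one transcript per gene).
    exons
        DataFrame with columns ``gene_id, start, end``; per gene the exon
        list must be sorted and disjoint and lie inside the gene interval.
    expected_class
        Optional Series of planted positional-class labels (synthetic
        catalogs only; ground truth for classifier tests).
    """

    transcripts: pd.DataFrame
    genes: pd.DataFrame
    exons: pd.DataFrame
    expected_class: pd.Series | None = None

    def __post_init__(self) -> None:
        t, g, e = self.transcripts, self.genes, self.exons
        if (t["start"] >= t["end"]).any():
            bad = t.index[t["start"] >= t["end"]]
            raise ValueError(f"zero/negative-length transcript intervals: {list(bad[:5])}")
        if (g["start"] >= g["end"]).any():
            raise ValueError("zero/negative-length gene intervals")
        if not e.empty:
            span = e.merge(g[["start", "end"]], left_on="gene_id",
                           right_index=True, suffixes=("", "_gene"))
            if ((span["start"] < span["start_gene"]) |
                    (span["end"] > span["end_gene"])).any():
                raise ValueError("exon outside its gene interval")
            for gid, grp in e.groupby("gene_id", sort=False):
                s = grp.sort_values("start")
                if (s["start"].values[1:] < s["end"].values[:-1]).any():
                    raise ValueError(f"overlapping/unsorted exons in gene {gid}")

    # -- views -------------------------------------------------------------
    @property
    def chromosomes(self) -> set[str]:
        return set(self.transcripts["chrom"]) | set(self.genes["chrom"])

    @property
    def lncrnas(self) -> pd.DataFrame:
        return self.transcripts[self.transcripts["biotype"] == LNCRNA]

    @property
    def mrnas(self) -> pd.DataFrame:
        return self.transcripts[self.transcripts["biotype"] == MRNA]

    def gene_tss(self) -> pd.Series:
        g = self.genes
        return pd.Series(np.where(g["strand"] == "+", g["start"], g["end"]),
                         index=g.index, name="tss")

    def introns(self) -> pd.DataFrame:
        """Intron intervals (gene_id, start, end) between consecutive exons."""
        rows = []
        for gid, grp in self.exons.groupby("gene_id", sort=False):
            s = grp.sort_values("start")
            starts = s["end"].values[:-1]
            ends = s["start"].values[1:]
            for a, b in zip(starts, ends):
                if a < b:
                    rows.append((gid, int(a), int(b)))
        return pd.DataFrame(rows, columns=["gene_id", "start", "end"])

    # -- plain-text IO -----------------------------------------------------
    def write_dir(self, outdir: str | Path) -> None:
        """BED-like transcript TSV + GFF-like exon TSV (+ expected labels)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bed = self.transcripts.reset_index(names="name")
        bed["score"] = 0
        bed[["chrom", "start", "end", "name", "score", "strand", "biotype"]].to_csv(
            outdir / "transcripts.bed.tsv", sep="\t", index=False)
        genes = self.genes.reset_index(names="gene_id")
        genes[["chrom", "start", "end", "gene_id", "strand"]].to_csv(
            outdir / "genes.tsv", sep="\t", index=False)
        self.exons.to_csv(outdir / "exons.tsv", sep="\t", index=False)
        if self.expected_class is not None:
            self.expected_class.rename("expected_class").to_csv(
                outdir / "expected_class.tsv", sep="\t", index_label="transcript_id")

    @classmethod
    def read_dir(cls, indir: str | Path) -> "TranscriptCatalog":
        indir = Path(indir)
        bed = pd.read_csv(indir / "transcripts.bed.tsv", sep="\t")
        transcripts = bed.set_index("name")[["chrom", "start", "end",
                                             "strand", "biotype"]]
        transcripts.index.name = "transcript_id"
        transcripts["chrom"] = transcripts["chrom"].astype(str)
        genes = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene_id")
        genes["chrom"] = genes["chrom"].astype(str)
        exons = pd.read_csv(indir / "exons.tsv", sep="\t")
        expected = None
        path = indir / "expected_class.tsv"
        if path.exists():
            expected = pd.read_csv(path, sep="\t",
                                   index_col="transcript_id")["expected_class"]
        return cls(transcripts, genes, exons, expected)
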