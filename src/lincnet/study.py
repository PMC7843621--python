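"""Expression-study container: intensity matrix + sample design + biotypes.

The matrix holds microarray-style intensities for transcripts (rows) across
plasma samples (columns). Samples belong to a two-factor design:
group (e.g. control / diabetic) x timepoint (e.g. 6wk / 20wk). Intensities
are carried either on the log2 scale (simulation default, microarray
convention) or on the linear scale, with an explicit scale flag so that
fold-change semantics never depend on guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LNCRNA = "lncRNA"
MRNA = "mRNA"
_SCALES = ("log2", "linear")


@dataclass
class ExpressionStudy:
    """Transcripts x samples intensities with the sample design.

    Parameters
    ----------
    intensities
        DataFrame indexed by transcript id, one column per sample.
    design
        DataFrame indexed by sample id with columns ``group`` and
        ``timepoint``; every intensity column must appear here.
    biotypes
        Series mapping transcript id -> {"lncRNA", "mRNA"}.
    scale
        "log2" or "linear".
    """

    intensities: pd.DataFrame
    design: pd.DataFrame
    biotypes: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate transcript ids in intensity table")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate sample ids in intensity table")
        missing = set(self.intensities.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples absent from design: {sorted(missing)[:5]}")
        for col in ("group", "timepoint"):
            if col not in self.design.columns:
                raise ValueError(f"design sheet lacks required column {col!r}")
        self.biotypes = self.biotypes.reindex(self.intensities.index)
        if self.biotypes.isna().any():
            bad = self.biotypes.index[self.biotypes.isna()]
            raise ValueError(f"transcripts without biotype: {list(bad[:5])}")

    # -- views -------------------------------------------------------------
    @property
    def transcripts(self) -> pd.Index:
        return self.intensities.index

    @property
    def timepoints(self) -> list[str]:
        return list(pd.unique(self.design["timepoint"]))

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.design["group"]))

    def samples_for(self, timepoint: str, group: str | None = None) -> list[str]:
        sel = self.design["timepoint"] == timepoint
        if group is not None:
            sel &= self.design["group"] == group
        cols = [s for s in self.intensities.columns if sel.get(s, False)]
        return cols

    def to_log2(self) -> "ExpressionStudy":
        if self.scale == "log2":
            return self
        vals = self.intensities.where(self.intensities > 0)
        return replace(self, intensities=np.log2(vals), scale="log2")

    def to_linear(self) -> "ExpressionStudy":
        if self.scale == "linear":
            return self
        return replace(self, intensities=2.0 ** self.intensities, scale="linear")

    def subset(self, transcripts) -> "ExpressionStudy":
        sub = self.intensities.loc[list(transcripts)]
        return replace(self, intensities=sub, biotypes=self.biotypes.loc[sub.index])


# -- plain-text IO (TSV, as written by the simulator) ----------------------

def write_expression_tsv(study: ExpressionStudy, path: str | Path) -> None:
    """First column = transcript id, remaining columns = samples."""
    study.intensities.to_csv(path, sep="\t", index_label="transcript_id")


def write_design_tsv(study: ExpressionStudy, path: str | Path) -> None:
    study.design.to_csv(path, sep="\t", index_label="sample")


def write_biotypes_tsv(study: ExpressionStudy, path: str | Path) -> None:
    study.biotypes.rename("biotype").to_csv(path, sep="\t",
                                            index_label="transcript_id")


def read_study(expr_path: str | Path, design_path: str | Path,
               biotypes: pd.Series | str | Path, scale: str = "log2",
               ) -> ExpressionStudy:
    """Load a study from the TSV triplet written by the simulator.

    ``biotypes`` may be a Series (e.g. ``catalog.transcripts["biotype"]``)
    or the path of a two-column transcript_id/biotype TSV.
    """
    tab = pd.read_csv(expr_path, sep="\t", index_col="transcript_id")
    design = pd.read_csv(design_path, sep="\t", index_col="sample")
    if not isinstance(biotypes, pd.Series):
        biotypes = pd.read_csv(biotypes, sep="\t",
                               index_col="transcript_id")["biotype"]
    return ExpressionStudy(tab, design, biotypes, scale=scale)
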