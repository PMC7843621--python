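"""Differential expression: normalisation, testing, thresholding, overlap.

The calling rule mirrors standard two-colour-array practice: a transcript
is deregulated when its linear-scale fold change (diabetic / control group
means) is >= ``fc_min`` or <= 1/``fc_min`` AND its p-value is <= ``p_max``
— both thresholds inclusive. The per-transcript test is the two-sided
Mann-Whitney U by default (exact when both groups have <= 8 samples and no
ties; tie-corrected normal approximation otherwise), with Welch's t
selectable; both appear in array workflows and the choice is surfaced as
configuration rather than resolved silently. Raw p is the default calling
column; Benjamini-Hochberg-adjusted calling is available and both counts
can always be reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .study import LNCRNA, MRNA, ExpressionStudy

logger = logging.getLogger(__name__)

TESTS = ("mann_whitney", "welch_t")


@dataclass
class DEResult:
    """Per-transcript differential-expression table plus the rule used.

    ``table`` is indexed by transcript id with columns ``biotype,
    fold_change, log2_fc, direction, p_raw, p_adj, deregulated, valid``
    (``valid`` is False for transcripts excluded from calling, e.g. a zero
    control mean on linear data).
    """

    table: pd.DataFrame
    timepoint: str
    test: str
    fc_min: float = 2.0
    p_max: float = 0.05
    p_column: str = "raw"

    def counts(self, biotype: str | None = None) -> tuple[int, int, int]:
        """(n_up, n_down, n_total) among deregulated transcripts."""
        t = self.table
        if biotype is not None:
            t = t[t["biotype"] == biotype]
        d = t[t["deregulated"]]
        n_up = int((d["direction"] == "up").sum())
        n_down = int((d["direction"] == "down").sum())
        return n_up, n_down, n_up + n_down

    def deregulated_ids(self, biotype: str | None = None) -> list[str]:
        t = self.table
        if biotype is not None:
            t = t[t["biotype"] == biotype]
        return list(t.index[t["deregulated"]])


@dataclass
class OverlapSummary:
    """Transcripts deregulated in both of two comparisons.

    Direction is taken from the second comparison; ``n_up + n_down``
    always equals ``n_overlap``.
    """

    ids: list[str]
    up_in_b: list[str]
    down_in_b: list[str]

    @property
    def n_overlap(self) -> int:
        return len(self.ids)

    @property
    def n_up(self) -> int:
        return len(self.up_in_b)

    @property
    def n_down(self) -> int:
        return len(self.down_in_b)


# ---------------------------------------------------------------------------
# normalisation

def quantile_normalize(study: ExpressionStudy,
                       max_missing_frac: float = 0.0) -> ExpressionStudy:
    """Force every sample onto the common row-mean reference distribution.

    Classic microarray quantile normalisation: the reference is the mean
    of the per-sample sorted intensity vectors; each sample's values are
    replaced by the reference value at their (average, tie-aware) rank.
    Rank order within a sample is preserved and the operation is
    idempotent on tie-free data.
    """
    X = study.intensities.to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        frac = n_missing / X.size
        if frac > max_missing_frac:
            raise ValueError(
                f"{frac:.3%} missing values exceed the allowed "
                f"{max_missing_frac:.3%}")
        logger.warning("filling %d missing values with row means", n_missing)
        row_means = np.nanmean(X, axis=1)
        ii, jj = np.where(np.isnan(X))
        X[ii, jj] = row_means[ii]
    n = X.shape[0]
    reference = np.sort(X, axis=0).mean(axis=1)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    out = np.interp(ranks, np.arange(1, n + 1), reference)
    intensities = pd.DataFrame(out, index=study.intensities.index,
                               columns=study.intensities.columns)
    return replace(study, intensities=intensities)


# ---------------------------------------------------------------------------
# fold change and tests

def fold_change(study: ExpressionStudy, timepoint: str,
                mean: str = "arithmetic") -> pd.DataFrame:
    """Linear-scale ratio (diabetic / control group means) per transcript.

    ``mean="arithmetic"`` averages linear intensities (vendor convention);
    ``"geometric"`` averages log2 values and exponentiates the difference.
    Ratios with a zero control mean come back infinite and ``valid=False``.
    """
    ctrl_grp, case_grp = study.groups[0], study.groups[1]
    ctrl = study.samples_for(timepoint, ctrl_grp)
    case = study.samples_for(timepoint, case_grp)
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError(
            f"need >=2 samples per group at timepoint {timepoint!r}")
    if mean == "arithmetic":
        lin = study.to_linear().intensities
        c = lin[ctrl].mean(axis=1)
        d = lin[case].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = d / c
        ratio = ratio.where(c > 0, np.inf)
    elif mean == "geometric":
        log2 = study.to_log2().intensities
        ratio = 2.0 ** (log2[case].mean(axis=1) - log2[ctrl].mean(axis=1))
    else:
        raise ValueError(f"unknown mean {mean!r}")
    valid = np.isfinite(ratio)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%d transcripts with undefined fold change excluded "
                       "from calling", n_bad)
    direction = pd.Series(np.where(ratio > 1, "up",
                                   np.where(ratio < 1, "down", "none")),
                          index=ratio.index)
    return pd.DataFrame({"fold_change": ratio,
                         "log2_fc": np.log2(ratio.where(ratio > 0)),
                         "direction": direction,
                         "valid": valid})


def test_transcript(study: ExpressionStudy, timepoint: str,
                    method: str = "mann_whitney") -> pd.DataFrame:
    """Two-sided per-transcript p-values comparing the two groups.

    Returns a DataFrame with ``p_raw`` and a ``degenerate`` flag set for
    transcripts constant across both groups (p forced to 1 there).
    """
    if method not in TESTS:
        raise ValueError(f"method must be one of {TESTS}")
    ctrl_grp, case_grp = study.groups[0], study.groups[1]
    log2 = study.to_log2().intensities
    X = log2[study.samples_for(timepoint, ctrl_grp)].to_numpy()
    Y = log2[study.samples_for(timepoint, case_grp)].to_numpy()
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise ValueError(
            f"need >=2 samples per group at timepoint {timepoint!r}")
    both = np.concatenate([X, Y], axis=1)
    degenerate = np.ptp(both, axis=1) == 0
    p = np.ones(X.shape[0])
    live = ~degenerate
    if live.any():
        if method == "welch_t":
            res = stats.ttest_ind(Y[live], X[live], axis=1, equal_var=False)
            p[live] = res.pvalue
        else:
            p[live] = _mann_whitney_p(X[live], Y[live])
    return pd.DataFrame({"p_raw": p, "degenerate": degenerate},
                        index=log2.index)


def _mann_whitney_p(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact MWU when both groups <= 8 and tie-free, else tie-corrected
    normal approximation (no continuity correction; see methods note)."""
    n1, n2 = X.shape[1], Y.shape[1]
    small = n1 <= 8 and n2 <= 8
    if not small:
        return stats.mannwhitneyu(X, Y, axis=1, method="asymptotic",
                                  use_continuity=False).pvalue
    both = np.concatenate([X, Y], axis=1)
    has_ties = np.array([len(np.unique(row)) < row.size for row in both])
    p = np.empty(X.shape[0])
    if (~has_ties).any():
        p[~has_ties] = np.atleast_1d(stats.mannwhitneyu(
            X[~has_ties], Y[~has_ties], axis=1, method="exact").pvalue)
    if has_ties.any():
        p[has_ties] = np.atleast_1d(stats.mannwhitneyu(
            X[has_ties], Y[has_ties], axis=1, method="asymptotic",
            use_continuity=False).pvalue)
    return p


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# calling

def run_de(study: ExpressionStudy, timepoint: str,
           test: str = "mann_whitney", fc_min: float = 2.0,
           p_max: float = 0.05, p_column: str = "raw",
           mean: str = "arithmetic") -> DEResult:
    """Fold change + test + BH + thresholding in one call."""
    fc = fold_change(study, timepoint, mean=mean)
    pt = test_transcript(study, timepoint, method=test)
    table = fc.join(pt)
    table["p_adj"] = adjust_bh(table["p_raw"].to_numpy())
    table.insert(0, "biotype", study.biotypes)
    de = DEResult(table, timepoint=timepoint, test=test)
    return call_deregulated(de, fc_min=fc_min, p_max=p_max, p_column=p_column)


def call_deregulated(de: DEResult, fc_min: float = 2.0, p_max: float = 0.05,
                     p_column: str = "raw") -> DEResult:
    """Apply the inclusive fold-change/p thresholds to a DEResult.

    up: ratio >= fc_min and p <= p_max; down: ratio <= 1/fc_min and
    p <= p_max. ``p_column`` chooses raw or BH-adjusted p.
    """
    if fc_min <= 1:
        raise ValueError("fc_min must exceed 1")
    if p_column not in ("raw", "adj"):
        raise ValueError("p_column must be 'raw' or 'adj'")
    t = de.table.copy()
    p = t["p_raw"] if p_column == "raw" else t["p_adj"]
    ratio = t["fold_change"]
    passing = (p <= p_max) & t["valid"]
    up = passing & (ratio >= fc_min)
    down = passing & (ratio <= 1.0 / fc_min)
    t["deregulated"] = up | down
    return replace(de, table=t, fc_min=fc_min, p_max=p_max, p_column=p_column)


def overlap_sets(de_a: DEResult, de_b: DEResult) -> OverlapSummary:
    """Deregulated-in-both ids, split by their direction in ``de_b``."""
    if not set(de_a.table.index) & set(de_b.table.index):
        raise ValueError("DE results share no transcript ids")
    a = set(de_a.deregulated_ids())
    b = de_b.table[de_b.table["deregulated"]]
    common = a & set(b.index)
    up = sorted(i for i in common if b.loc[i, "direction"] == "up")
    down = sorted(i for i in common if b.loc[i, "direction"] == "down")
    return OverlapSummary(sorted(common), up, down)


# ---------------------------------------------------------------------------
# presentation helpers

@dataclass
class ClusterResult:
    """Leaf orderings for a deregulated-transcript heat map."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    description: str = ("average linkage on 1 - Pearson correlation of "
                        "row-standardised log2 intensities")


def _corr_distance(M: np.ndarray) -> np.ndarray:
    """1 - Pearson distance matrix; zero-variance rows sit at distance 2."""
    sd = M.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance rows set to maximal distance",
                       int(flat.sum()))
    Z = (M - M.mean(axis=1, keepdims=True))
    norm = np.linalg.norm(Z, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    Z = Z / norm
    D = 1.0 - Z @ Z.T
    D[flat, :] = 2.0
    D[:, flat] = 2.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def hierarchical_cluster(study: ExpressionStudy, transcripts,
                         cluster_samples: bool = True) -> ClusterResult:
    """Agglomerative ordering of a transcript subset (and its samples).

    Deterministic for a fixed input order; scipy's linkage breaks distance
    ties by merge index, i.e. first-come order.
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("empty transcript subset")
    log2 = study.to_log2().intensities.loc[transcripts]
    M = log2.to_numpy(dtype=float)
    if len(transcripts) == 1:
        return ClusterResult(transcripts, list(log2.columns),
                             np.empty((0, 4)), np.empty((0, 4)))
    Zr = linkage(squareform(_corr_distance(M), checks=False),
                 method="average")
    row_order = [transcripts[i] for i in leaves_list(Zr)]
    cols = list(log2.columns)
    if cluster_samples and len(cols) > 1:
        Zc = linkage(squareform(_corr_distance(M.T), checks=False),
                     method="average")
        col_order = [cols[i] for i in leaves_list(Zc)]
    else:
        Zc = np.empty((0, 4))
        col_order = cols
    return ClusterResult(row_order, col_order, Zr, Zc)


def volcano_table(de: DEResult) -> pd.DataFrame:
    """(log2 fold change, -log10 p, deregulated) per tested transcript."""
    t = de.table
    p = t["p_raw"] if de.p_column == "raw" else t["p_adj"]
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(p)
    return pd.DataFrame({"log2_fc": t["log2_fc"],
                         "neg_log10_p": neg_log10,
                         "deregulated": t["deregulated"]}, index=t.index)
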