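"""Seeded synthetic plasma-microarray studies with known planted truth.

The generator emulates a two-condition (control vs diabetic), two-timepoint
(6 wk = diabetes without cardiomyopathy, 20 wk = diabetic cardiomyopathy)
circulating lncRNA/mRNA profiling experiment on the mouse karyotype
(chromosomes 1..19 + X):

* per-transcript genomic annotation in which every positional lncRNA class
  is represented with a stored expected label (classifier ground truth);
* log2-normal intensities with planted differentially expressed transcripts
  at a configurable linear fold-change range;
* planted hub lncRNAs, each sharing a latent factor with a block of mRNAs
  so that hub-block Pearson correlations approach +-1 as the residual noise
  vanishes; the hub's group effect is routed through the latent factor, so
  block members inherit their planted fold changes coherently;
* a gene-set catalog over the three GO namespaces plus pathways, with
  planted terms overlapping the hub blocks by a configurable fraction.

Every random draw flows from ``SimulationConfig.seed``; the same config is
guaranteed to reproduce the same study bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import child_rng
from .annotation import CLASS_LABELS
from .catalog import TranscriptCatalog
from .genesets import GO_NAMESPACES, PATHWAY, GeneSetCatalog
from .study import LNCRNA, MRNA, ExpressionStudy, write_biotypes_tsv, \
    write_design_tsv, write_expression_tsv

# Positional-class mix used when building catalogs, loosely shaped like the
# vendor-annotation proportions reported for deregulated plasma lncRNAs
# (intergenic-dominant, then exon sense overlapping).
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "intergenic": 0.40,
    "exon sense overlapping": 0.32,
    "intronic antisense": 0.11,
    "natural antisense": 0.07,
    "bidirectional": 0.05,
    "intron sense overlapping": 0.05,
}

_GENE_LEN = 8000
_GENE_SPACING = 40000
_EXON_OFFSETS = ((0, 1000), (3000, 4000), (7000, 8000))


def _as_updown(value, timepoints) -> dict[str, tuple[int, int]]:
    """Normalise a planted-DE count argument to {timepoint: (n_up, n_down)}."""
    if isinstance(value, int):
        value = {tp: value for tp in timepoints}
    out = {}
    for tp in timepoints:
        v = value.get(tp, 0)
        if isinstance(v, int):
            out[tp] = (v - v // 2, v // 2)
        else:
            up, down = v
            out[tp] = (int(up), int(down))
    return out


@dataclass
class SimulationConfig:
    """Study-design constants for the synthetic generator.

    Defaults mirror the profiled study: 24,881 mRNA transcripts, 12
    samples per group, timepoints 6wk/20wk, planted deregulated counts
    equal to the printed up/down totals per timepoint, 33 lncRNAs planted
    as deregulated at both timepoints (19 up / 14 down at 20wk), and five
    hub lncRNAs each driving a 104-mRNA correlation block at the
    cardiomyopathy timepoint. The lncRNA probe count is not a reported
    value; 30,000 is a realistic array scale.
    """

    n_lnc: int = 30000
    n_mrna: int = 24881
    n_per_group: int = 12
    timepoints: tuple[str, ...] = ("6wk", "20wk")
    groups: tuple[str, str] = ("control", "diabetic")
    n_de_lnc: dict | int = field(
        default_factory=lambda: {"6wk": (92, 60), "20wk": (1495, 1860)})
    n_de_mrna: dict | int = field(
        default_factory=lambda: {"6wk": (62, 65), "20wk": (1052, 1528)})
    n_shared_de_lnc: tuple[int, int] = (19, 14)
    planted_fc_range: tuple[float, float] = (2.5, 6.0)
    n_hubs: int = 5
    hub_block_size: int = 104
    hub_noise_sd: float = 0.02
    hub_latent_sd: float = 0.5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 0.25
    transcript_mean_sd: float = 1.5
    n_chromosomes: int = 20
    chr2_de_share: float = 0.10
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    bidirectional_window: int = 1000
    n_go_terms: int = 150
    n_pathway_terms: int = 100
    term_size_range: tuple[int, int] = (10, 200)
    term_overlap_frac: float = 1.0
    de_fc_threshold: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_lnc", "n_mrna", "n_per_group", "hub_block_size",
                     "n_chromosomes", "n_go_terms", "n_pathway_terms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_hubs < 0:
            raise ValueError("n_hubs must be >= 0")
        if self.planted_fc_range[0] < self.de_fc_threshold:
            raise ValueError(
                "planted_fc_range lower bound must be >= the downstream "
                f"fold-change threshold ({self.de_fc_threshold})")
        if unknown := set(self.class_proportions) - set(CLASS_LABELS):
            raise ValueError(f"unknown positional classes: {sorted(unknown)}")
        de = self.de_lnc_counts()
        dcm_up = de[self.dcm_timepoint][0]
        if self.n_hubs > dcm_up + de[self.dcm_timepoint][1]:
            raise ValueError("n_hubs exceeds planted DE lncRNAs at the "
                             "cardiomyopathy timepoint")

    @property
    def dcm_timepoint(self) -> str:
        return self.timepoints[-1]

    def de_lnc_counts(self) -> dict[str, tuple[int, int]]:
        return _as_updown(self.n_de_lnc, self.timepoints)

    def de_mrna_counts(self) -> dict[str, tuple[int, int]]:
        return _as_updown(self.n_de_mrna, self.timepoints)

    def chromosome_labels(self) -> list[str]:
        # mouse-style karyotype: autosomes then X
        return [str(i) for i in range(1, self.n_chromosomes)] + ["X"]


@dataclass
class PlantedTruth:
    """Ground truth planted into a simulated study.

    ``de_lnc`` / ``de_mrna`` map timepoint -> {"up": [...], "down": [...]};
    ``hub_blocks`` maps each hub lncRNA to its correlated mRNA block and
    ``hub_signs`` to each member's correlation sign; ``enriched_terms``
    maps each hub to the gene-set terms planted over its block.
    """

    de_lnc: dict[str, dict[str, list[str]]]
    de_mrna: dict[str, dict[str, list[str]]]
    hub_blocks: dict[str, list[str]]
    hub_signs: dict[str, dict[str, int]]
    dcm_timepoint: str
    enriched_terms: dict[str, list[str]] = field(default_factory=dict)

    def de_ids(self, timepoint: str, biotype: str = LNCRNA) -> set[str]:
        d = self.de_lnc if biotype == LNCRNA else self.de_mrna
        return set(d[timepoint]["up"]) | set(d[timepoint]["down"])

    @property
    def hub_ids(self) -> list[str]:
        return list(self.hub_blocks)


# ---------------------------------------------------------------------------
# catalog

def generate_catalog(config: SimulationConfig) -> TranscriptCatalog:
    """Annotated transcript catalog with every positional class realised.

    Coding genes are laid down on each chromosome with wide spacing and a
    fixed three-exon structure; each lncRNA is then constructed relative
    to a host gene so that its positional class is known by construction
    (the expected labels ship with the catalog for classifier tests).
    """
    if config.seed is None:
        raise ValueError("SimulationConfig.seed must be set (reproducibility)")
    rng = child_rng(config.seed, 0)
    chroms = config.chromosome_labels()

    # genes: round-robin over chromosomes, sequential placement
    n_genes = config.n_mrna
    gene_chrom = [chroms[i % len(chroms)] for i in range(n_genes)]
    per_chrom_idx: dict[str, int] = {c: 0 for c in chroms}
    gstart = np.empty(n_genes, dtype=np.int64)
    for i, c in enumerate(gene_chrom):
        gstart[i] = 10000 + per_chrom_idx[c] * (_GENE_LEN + _GENE_SPACING)
        per_chrom_idx[c] += 1
    gend = gstart + _GENE_LEN
    gstrand = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    gene_ids = [f"MRNA{i:06d}" for i in range(n_genes)]
    genes = pd.DataFrame({"chrom": gene_chrom, "start": gstart, "end": gend,
                          "strand": gstrand},
                         index=pd.Index(gene_ids, name="gene_id"))
    exons = pd.DataFrame(
        [(gid, int(s0 + a), int(s0 + b))
         for gid, s0 in zip(gene_ids, gstart) for a, b in _EXON_OFFSETS],
        columns=["gene_id", "start", "end"])

    # class allocation by largest remainder on the configured proportions
    props = config.class_proportions
    counts = {c: int(math.floor(props.get(c, 0.0) * config.n_lnc))
              for c in CLASS_LABELS}
    leftover = config.n_lnc - sum(counts.values())
    order = sorted(CLASS_LABELS,
                   key=lambda c: props.get(c, 0.0) * config.n_lnc
                   - counts[c], reverse=True)
    for c in order[:leftover]:
        counts[c] += 1
    missing = [c for c in CLASS_LABELS if props.get(c, 0) > 0 and counts[c] == 0]
    if missing:
        raise ValueError(
            "n_lnc too small to realise requested positional classes; "
            f"missing: {missing}")

    labels = [c for c in CLASS_LABELS for _ in range(counts[c])]
    rng.shuffle(labels)
    host = rng.integers(0, n_genes, size=config.n_lnc)

    ls = np.empty(config.n_lnc, dtype=np.int64)
    le = np.empty(config.n_lnc, dtype=np.int64)
    lstrand = np.empty(config.n_lnc, dtype=object)
    lchrom = np.empty(config.n_lnc, dtype=object)
    for i, lab in enumerate(labels):
        h = host[i]
        s0, s1, hs = gstart[h], gend[h], gstrand[h]
        lchrom[i] = gene_chrom[h]
        opp = "-" if hs == "+" else "+"
        if lab == "exon sense overlapping":
            ls[i], le[i], lstrand[i] = s0 + 3200, s0 + 3800, hs
        elif lab == "intron sense overlapping":
            ls[i], le[i], lstrand[i] = s0 + 4500, s0 + 5500, hs
        elif lab == "intronic antisense":
            ls[i], le[i], lstrand[i] = s0 + 4500, s0 + 5500, opp
        elif lab == "natural antisense":
            ls[i], le[i], lstrand[i] = s0 + 3200, s0 + 4200, opp
        elif lab == "bidirectional":
            off = int(rng.integers(200, config.bidirectional_window - 100))
            if hs == "+":
                ls[i], le[i] = s0 - off - 600, s0 - off
                lstrand[i] = "-"  # TSS = end, |end - gene TSS| = off
            else:
                ls[i], le[i] = s1 + off, s1 + off + 600
                lstrand[i] = "+"  # TSS = start
        else:  # intergenic: mid-gap, far beyond the bidirectional window
            ls[i], le[i] = s1 + 18000, s1 + 18600
            lstrand[i] = "+" if rng.random() < 0.5 else "-"

    lnc_ids = [f"LNC{i:06d}" for i in range(config.n_lnc)]
    lnc = pd.DataFrame({"chrom": lchrom, "start": ls, "end": le,
                        "strand": lstrand, "biotype": LNCRNA},
                       index=pd.Index(lnc_ids, name="transcript_id"))
    mrna = genes.assign(biotype=MRNA)
    mrna.index = mrna.index.rename("transcript_id")
    transcripts = pd.concat([lnc, mrna[["chrom", "start", "end", "strand",
                                        "biotype"]]])
    expected = pd.Series(labels, index=lnc.index, name="expected_class")
    return TranscriptCatalog(transcripts, genes, exons, expected)


# ---------------------------------------------------------------------------
# expression

def _pick(rng, pool, k):
    pool = np.asarray(sorted(pool))
    k = min(k, len(pool))
    return [str(x) for x in rng.choice(pool, size=k, replace=False)]


def _select_de(rng, ids, chroms, n_up, n_down, chr2_share, exclude=()):
    """Choose planted up/down sets, biasing a share onto chromosome 2."""
    avail = [i for i in ids if i not in exclude]
    on2 = [i for i in avail if chroms.get(i) == "2"]
    chosen: list[str] = []
    out = {}
    for key, n in (("up", n_up), ("down", n_down)):
        forced = _pick(rng, set(on2) - set(chosen), round(chr2_share * n))
        chosen += forced
        rest = _pick(rng, set(avail) - set(chosen), n - len(forced))
        chosen += rest
        out[key] = sorted(forced + rest)
    return out


def simulate_expression(catalog: TranscriptCatalog, config: SimulationConfig,
                        ) -> tuple[ExpressionStudy, PlantedTruth]:
    """Simulate log2 intensities with planted DE transcripts and hubs.

    Per-transcript baselines spread with ``transcript_mean_sd`` around
    ``baseline_log2_mean``; per-sample noise has sd ``baseline_log2_sd``.
    Planted DE transcripts shift the diabetic group mean by +-log2(fc)
    with fc drawn uniformly from ``planted_fc_range``. At the
    cardiomyopathy timepoint each hub lncRNA and its block replace their
    noise with a shared latent factor (sd ``hub_latent_sd`` plus the
    group shift) and residual sd ``hub_noise_sd``, so pairwise Pearson r
    -> +-1 as the residual vanishes.
    """
    if config.seed is None:
        raise ValueError("SimulationConfig.seed must be set (reproducibility)")
    rng = child_rng(config.seed, 1)
    tps, (ctrl, diab) = config.timepoints, config.groups
    n = config.n_per_group

    samples, design_rows = [], []
    for tp in tps:
        for grp in (ctrl, diab):
            for i in range(n):
                sid = f"{grp}_{tp}_{i + 1:02d}"
                samples.append(sid)
                design_rows.append((sid, grp, tp))
    design = pd.DataFrame(design_rows, columns=["sample", "group",
                                                "timepoint"]).set_index("sample")

    ids = catalog.transcripts.index
    chrom_of = catalog.transcripts["chrom"].to_dict()
    lnc_ids = list(catalog.lncrnas.index)
    mrna_ids = list(catalog.mrnas.index)
    n_t, n_s = len(ids), len(samples)

    baseline = rng.normal(config.baseline_log2_mean,
                          config.transcript_mean_sd, size=n_t)
    X = baseline[:, None] + rng.normal(0.0, config.baseline_log2_sd,
                                       size=(n_t, n_s))
    row = {t: i for i, t in enumerate(ids)}
    col = {s: j for j, s in enumerate(samples)}

    de_lnc_counts = config.de_lnc_counts()
    de_mrna_counts = config.de_mrna_counts()
    de_lnc: dict[str, dict[str, list[str]]] = {}
    de_mrna: dict[str, dict[str, list[str]]] = {}

    first_tp = tps[0]
    for tp in tps:
        up_n, down_n = de_lnc_counts[tp]
        if tp == config.dcm_timepoint and tp != first_tp and de_lnc.get(first_tp):
            sh_up, sh_down = config.n_shared_de_lnc
            pool = sorted(set(de_lnc[first_tp]["up"]) |
                          set(de_lnc[first_tp]["down"]))
            shared = _pick(rng, pool, min(sh_up + sh_down, len(pool), up_n + down_n))
            shared_up, shared_down = shared[:sh_up], shared[sh_up:]
            # non-shared picks exclude the whole first-timepoint DE set so
            # the planted cross-timepoint overlap is exactly n_shared_de_lnc
            sel = _select_de(rng, lnc_ids, chrom_of,
                             max(up_n - len(shared_up), 0),
                             max(down_n - len(shared_down), 0),
                             config.chr2_de_share, exclude=set(pool))
            de_lnc[tp] = {"up": sorted(sel["up"] + shared_up),
                          "down": sorted(sel["down"] + shared_down)}
        else:
            de_lnc[tp] = _select_de(rng, lnc_ids, chrom_of, up_n, down_n,
                                    config.chr2_de_share)
        m_up, m_down = de_mrna_counts[tp]
        de_mrna[tp] = {"up": _pick(rng, mrna_ids, m_up)}
        de_mrna[tp]["down"] = _pick(rng, set(mrna_ids) - set(de_mrna[tp]["up"]),
                                    m_down)
        de_mrna[tp] = {k: sorted(v) for k, v in de_mrna[tp].items()}

        # apply planted group-mean shifts on the diabetic samples of tp
        diab_cols = [col[s] for s, r in design.iterrows()
                     if r["timepoint"] == tp and r["group"] == diab]
        fc_lo, fc_hi = config.planted_fc_range
        planted_fc: dict[str, float] = {}
        for direction, sign in (("up", 1.0), ("down", -1.0)):
            for tid in de_lnc[tp][direction] + de_mrna[tp][direction]:
                fc = float(rng.uniform(fc_lo, fc_hi))
                planted_fc[tid] = fc
                X[row[tid], diab_cols] += sign * math.log2(fc)
        if tp == config.dcm_timepoint:
            dcm_planted_fc = planted_fc

    # hubs at the cardiomyopathy timepoint (up-regulated, as in the study)
    dcm = config.dcm_timepoint
    hub_blocks: dict[str, list[str]] = {}
    hub_signs: dict[str, dict[str, int]] = {}
    if config.n_hubs > 0:
        hub_pool = de_lnc[dcm]["up"] or de_lnc[dcm]["down"]
        hub_dir = 1.0 if de_lnc[dcm]["up"] else -1.0
        if not hub_pool:
            raise ValueError("n_hubs > 0 but no planted DE lncRNAs at the "
                             "cardiomyopathy timepoint")
        hubs = _pick(rng, hub_pool, config.n_hubs)
        block_pool = list(de_mrna[dcm]["up"])
        rng.shuffle(block_pool)
        tp_cols = [col[s] for s, r in design.iterrows()
                   if r["timepoint"] == dcm]
        is_diab = np.array([design.loc[samples[j], "group"] == diab
                            for j in tp_cols], dtype=float)
        for h in hubs:
            block = block_pool[:config.hub_block_size]
            block_pool = block_pool[config.hub_block_size:]
            hub_blocks[h] = sorted(block)
            delta = hub_dir * math.log2(dcm_planted_fc[h])
            hub_signs[h] = {m: (1 if delta > 0 else -1) for m in hub_blocks[h]}
            u = rng.normal(0.0, 1.0, size=len(tp_cols))
            z = config.hub_latent_sd * u + delta * is_diab
            X[row[h], tp_cols] = baseline[row[h]] + z + rng.normal(
                0.0, config.hub_noise_sd, size=len(tp_cols))
            for m in hub_blocks[h]:
                # group shift of the member stays +log2(fc_m) (up-regulated);
                # its correlation sign with the hub is sign(lam)
                lam = math.log2(dcm_planted_fc[m]) / delta
                X[row[m], tp_cols] = baseline[row[m]] + lam * z + rng.normal(
                    0.0, config.hub_noise_sd, size=len(tp_cols))

    intensities = pd.DataFrame(X, index=ids, columns=samples)
    study = ExpressionStudy(intensities, design,
                            catalog.transcripts["biotype"], scale="log2")
    truth = PlantedTruth(de_lnc, de_mrna, hub_blocks, hub_signs, dcm)
    return study, truth


# ---------------------------------------------------------------------------
# gene sets

def generate_gene_sets(catalog: TranscriptCatalog, config: SimulationConfig,
                       truth: PlantedTruth | None = None) -> GeneSetCatalog:
    """GMT-style catalog over BP/CC/MF + pathway namespaces.

    When ``truth`` is given, one term per namespace is planted over each
    hub's mRNA block: a fraction ``term_overlap_frac`` of the term comes
    from the block, the remainder is random filler (at fraction 1.0 the
    term IS the block). Remaining terms are random draws from the mRNA
    universe with sizes uniform in ``term_size_range``.
    """
    if config.seed is None:
        raise ValueError("SimulationConfig.seed must be set (reproducibility)")
    rng = child_rng(config.seed, 2)
    universe = sorted(catalog.mrnas.index)
    lo, hi = config.term_size_range
    if hi > len(universe):
        raise ValueError(
            f"requested term size up to {hi} exceeds the {len(universe)}-gene "
            "universe")

    sets: dict[str, frozenset[str]] = {}
    namespaces: dict[str, str] = {}
    planted: dict[str, list[str]] = {}

    if truth is not None:
        frac = config.term_overlap_frac
        for hub in truth.hub_ids:
            block = truth.hub_blocks[hub]
            planted[hub] = []
            for ns in GO_NAMESPACES + (PATHWAY,):
                term = f"{ns}:planted:{hub}"
                n_core = max(1, round(frac * len(block)))
                core = _pick(rng, block, n_core)
                filler = _pick(rng, set(universe) - set(block),
                               len(block) - n_core)
                sets[term] = frozenset(core + filler)
                namespaces[term] = ns
                planted[hub].append(term)

    for ns in GO_NAMESPACES + (PATHWAY,):
        n_terms = (config.n_go_terms if ns in GO_NAMESPACES
                   else config.n_pathway_terms)
        for i in range(n_terms):
            term = f"{ns}:{i:04d}"
            size = int(rng.integers(lo, hi + 1))
            sets[term] = frozenset(_pick(rng, universe, size))
            namespaces[term] = ns

    if truth is not None:
        truth.enriched_terms = planted
    return GeneSetCatalog(sets, namespaces, planted)


# ---------------------------------------------------------------------------
# one-stop writer

def simulate_study(config: SimulationConfig):
    """Catalog + expression + truth + gene sets in one seeded call."""
    catalog = generate_catalog(config)
    study, truth = simulate_expression(catalog, config)
    gene_sets = generate_gene_sets(catalog, config, truth)
    return catalog, study, truth, gene_sets


def write_study_dir(outdir: str | Path, catalog: TranscriptCatalog,
                    study: ExpressionStudy, gene_sets: GeneSetCatalog) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(study, outdir / "expression.tsv")
    write_design_tsv(study, outdir / "design.tsv")
    write_biotypes_tsv(study, outdir / "biotypes.tsv")
    catalog.write_dir(outdir / "catalog")
    gene_sets.write_gmt(outdir / "gene_sets.gmt")
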