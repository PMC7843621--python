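"""End-to-end seeded run: simulate -> DE -> annotate -> network -> enrich.

One configured call produces every stage output plus a consolidated
report of the study-style summary numbers (deregulated counts per biotype
and timepoint, cross-timepoint overlap, chromosomal distribution, the
positional-class mix, hub list with partner counts, and the kappa-grouped
term table). The machine-readable report is canonical JSON — identical
config + seed reproduces it byte for byte — and every printed number is
recomputable from the stage outputs it summarises.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .annotation import chromosome_distribution, class_distribution, \
    classify_all
from .catalog import TranscriptCatalog
from .coexpression import build_network, export_network, extract_subnetwork, \
    rank_hubs
from .diffexpr import DEResult, overlap_sets, quantile_normalize, run_de, \
    volcano_table
from .enrichment import enrich_all, group_terms, hub_go_profile
from .genesets import GeneSetCatalog
from .simulate import PlantedTruth, SimulationConfig, simulate_study, \
    write_study_dir
from .study import LNCRNA, MRNA, ExpressionStudy, read_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class StageToggles:
    normalize: bool = True
    de: bool = True
    annotate: bool = True
    network: bool = True
    enrich: bool = True


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, round-trippable through JSON.

    Either ``simulation`` is set (synthetic run) or the four input paths
    are (real data: expression TSV, design TSV, catalog directory, GMT).
    """

    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    design_path: str | None = None
    biotypes_path: str | None = None
    catalog_dir: str | None = None
    gmt_path: str | None = None
    out_dir: str | None = None
    seed: int | None = None
    test: str = "mann_whitney"
    fc_min: float = 2.0
    p_max: float = 0.05
    p_column: str = "raw"
    r_threshold: float = 0.995
    network_p_threshold: float = 0.05
    top_k: int = 5
    kappa_threshold: float = 0.03
    enrich_p_max: float = 0.05
    bidirectional_window: int = 1000
    stages: StageToggles = field(default_factory=StageToggles)

    def __post_init__(self) -> None:
        if not (1 < self.fc_min):
            raise ValueError("fc_min must exceed 1")
        for name in ("p_max", "network_p_threshold", "enrich_p_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 < self.r_threshold <= 1):
            raise ValueError("r_threshold must lie in (0, 1]")
        if self.simulation is not None and self.seed is not None:
            self.simulation.seed = self.seed
        if self.simulation is not None and self.seed is None:
            self.seed = self.simulation.seed

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        # canonical JSON types (tuples -> lists) so round-trips compare equal
        return json.loads(json.dumps(asdict(self)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            sim = dict(d["simulation"])
            for key in ("timepoints", "groups", "planted_fc_range",
                        "n_shared_de_lnc", "term_size_range"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            for key in ("n_de_lnc", "n_de_mrna"):
                if isinstance(sim.get(key), dict):
                    sim[key] = {tp: tuple(v) if isinstance(v, list) else v
                                for tp, v in sim[key].items()}
            d["simulation"] = SimulationConfig(**sim)
        if isinstance(d.get("stages"), dict):
            d["stages"] = StageToggles(**d["stages"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read JSON (or TOML, read-only) run configuration."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib
            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Return value of :func:`run_pipeline`.

    ``report`` is the nested summary dict (serialised as report.json);
    the stage tables are kept for programmatic use and verification.
    """

    report: dict
    study: ExpressionStudy
    catalog: TranscriptCatalog | None
    gene_sets: GeneSetCatalog | None
    truth: PlantedTruth | None
    de_results: dict[str, DEResult]
    networks: dict[str, object]
    hub_rankings: dict[str, object]

    def report_json(self) -> str:
        return json.dumps(self.report, indent=2, sort_keys=True) + "\n"


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured stages and assemble the run report."""
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": {
            "fc_min": config.fc_min, "p_max": config.p_max,
            "p_column": config.p_column, "test": config.test,
            "r_threshold": config.r_threshold,
            "network_p_threshold": config.network_p_threshold,
            "top_k": config.top_k,
            "kappa_threshold": config.kappa_threshold,
            "enrich_p_max": config.enrich_p_max,
            "bidirectional_window": config.bidirectional_window,
        },
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    catalog, study, truth, gene_sets = _load_inputs(config)
    if out_dir and config.simulation is not None:
        write_study_dir(out_dir / "inputs", catalog, study, gene_sets)

    if config.stages.normalize:
        study = _stage("normalize")(quantile_normalize)(study)

    de_results: dict[str, DEResult] = {}
    networks: dict[str, object] = {}
    hub_rankings: dict[str, object] = {}
    timepoints = study.timepoints

    if config.stages.de:
        report["differential_expression"] = {}
        for tp in timepoints:
            de = _stage("differential_expression")(run_de)(
                study, tp, test=config.test, fc_min=config.fc_min,
                p_max=config.p_max, p_column=config.p_column)
            de_results[tp] = de
            entry = {}
            for biotype in (LNCRNA, MRNA):
                up, down, total = de.counts(biotype)
                entry[biotype] = {
                    "n_up": up, "n_down": down, "n_total": total,
                    "called_ids": sorted(de.deregulated_ids(biotype)),
                }
            report["differential_expression"][tp] = entry
            if out_dir:
                de.table.to_csv(out_dir / f"de_{tp}.tsv", sep="\t",
                                index_label="transcript_id")
                volcano_table(de).to_csv(out_dir / f"volcano_{tp}.tsv",
                                         sep="\t", index_label="transcript_id")
        if len(timepoints) >= 2:
            # cross-timepoint overlap is a lncRNA statistic
            lnc_a, lnc_b = (
                DEResult(de.table[de.table["biotype"] == LNCRNA],
                         de.timepoint, de.test, de.fc_min, de.p_max,
                         de.p_column)
                for de in (de_results[timepoints[0]],
                           de_results[timepoints[1]]))
            ov = _stage("overlap")(overlap_sets)(lnc_a, lnc_b)
            report["overlap"] = {
                "n_overlap": ov.n_overlap, "n_up": ov.n_up,
                "n_down": ov.n_down, "ids": ov.ids,
            }

    if config.stages.annotate and catalog is not None and de_results:
        report["annotation"] = {}
        labels = _stage("annotate")(classify_all)(
            catalog.lncrnas, catalog, config.bidirectional_window)
        if out_dir:
            labels.to_csv(out_dir / "lnc_classes.tsv", sep="\t",
                          index_label="transcript_id")
        for tp, de in de_results.items():
            summary = _stage("annotate")(chromosome_distribution)(
                de, catalog, biotype=LNCRNA)
            dereg = de.deregulated_ids(LNCRNA)
            dist = (class_distribution(labels.loc[dereg]).to_dict()
                    if dereg else {})
            arg = summary.argmax
            row = (summary.table.loc[arg]
                   if arg in summary.table.index else None)
            report["annotation"][tp] = {
                "argmax_chromosome": arg,
                "argmax_counts": {
                    "n_up": int(row["n_up"]) if row is not None else 0,
                    "n_down": int(row["n_down"]) if row is not None else 0,
                    "pct_up": float(row["pct_up"]) if row is not None else 0.0,
                    "pct_down": (float(row["pct_down"])
                                 if row is not None else 0.0),
                },
                "total_up": summary.total_up,
                "total_down": summary.total_down,
                "class_distribution_pct": dist,
            }
            if out_dir:
                summary.table.to_csv(out_dir / f"chromosomes_{tp}.tsv",
                                     sep="\t")

    if config.stages.network and de_results:
        report["network"] = {}
        for tp, de in de_results.items():
            lnc_ids = de.deregulated_ids(LNCRNA)
            mrna_ids = de.deregulated_ids(MRNA)
            direction = de.table["direction"]
            net = _stage("network")(build_network)(
                lnc_ids, mrna_ids, study, timepoint=tp,
                r_threshold=config.r_threshold,
                p_threshold=config.network_p_threshold, direction=direction)
            ranking = _stage("network")(rank_hubs)(net, k=config.top_k) \
                if net.n_edges else None
            networks[tp] = net
            hub_rankings[tp] = ranking
            entry = {"n_edges": net.n_edges}
            if ranking is not None and ranking.hubs:
                sub, n_partners = extract_subnetwork(net, ranking.hubs)
                networks[f"{tp}:hubs"] = sub
                entry.update({
                    "hubs": [{"id": h, "degree": ranking.degrees[h]}
                             for h in ranking.hubs],
                    "tied_at_k": ranking.tied_at_k,
                    "shortfall": ranking.shortfall,
                    "n_distinct_mrna_partners": n_partners,
                })
                if out_dir:
                    export_network(net, out_dir / f"network_{tp}.tsv", "tsv")
                    export_network(sub, out_dir / f"hub_network_{tp}.sif",
                                   "sif")
                    export_network(sub, out_dir / f"hub_network_{tp}.graphml",
                                   "graphml")
            report["network"][tp] = entry

    if config.stages.enrich and gene_sets is not None and networks:
        dcm = timepoints[-1]
        sub = networks.get(f"{dcm}:hubs")
        if sub is not None and sub.n_edges:
            measured = set(study.transcripts)
            background = gene_sets.genes() & measured
            partners = set(sub.edges["mrna"]) & background
            if partners:
                enr = _stage("enrich")(enrich_all)(
                    partners, gene_sets, background,
                    p_max=config.enrich_p_max)
                sig = enr.significant_terms()
                entry = {"n_significant_terms": len(sig),
                         "significant_terms": sorted(sig)}
                if sig:
                    grouping = _stage("enrich")(group_terms)(
                        enr, gene_sets, background,
                        kappa_threshold=config.kappa_threshold)
                    entry["groups"] = [
                        {"leading_term": grp["leading_term"],
                         "leading_p": grp["leading_p"],
                         "n_terms": len(grp["terms"]),
                         "terms": grp["terms"]}
                        for grp in grouping.groups]
                profile = _stage("enrich")(hub_go_profile)(
                    sub, gene_sets, background, p_max=config.enrich_p_max)
                entry["hub_profiles"] = {
                    hub: sorted(grp["term"])
                    for hub, grp in profile.table.groupby("hub")}
                entry["hubs_without_terms"] = profile.empty_hubs
                report["enrichment"] = {dcm: entry}
                if out_dir:
                    enr.table.to_csv(out_dir / f"enrichment_{dcm}.tsv",
                                     sep="\t")

    if out_dir:
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        (out_dir / "report.txt").write_text(render_text_report(report))
    return PipelineResult(report, study, catalog, gene_sets, truth,
                          de_results, networks, hub_rankings)


@_stage("load_inputs")
def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed is None:
            raise ValueError("simulation requires a seed")
        return simulate_study(sim)
    if not (config.expression_path and config.design_path):
        raise ValueError("either simulation or expression/design paths "
                         "must be configured")
    catalog = (TranscriptCatalog.read_dir(config.catalog_dir)
               if config.catalog_dir else None)
    if config.biotypes_path:
        biotypes = config.biotypes_path
    elif catalog is not None:
        biotypes = catalog.transcripts["biotype"]
    else:
        raise ValueError("biotypes_path or catalog_dir required to assign "
                         "transcript biotypes")
    study = read_study(config.expression_path, config.design_path, biotypes)
    gene_sets = (GeneSetCatalog.read_gmt(config.gmt_path)
                 if config.gmt_path else None)
    return catalog, study, None, gene_sets


def render_text_report(report: dict) -> str:
    """Human-readable mirror of the JSON report."""
    lines = [f"lincnet {report['version']}  (config {report['config_hash']}, "
             f"seed {report['seed']})"]
    for tp, entry in report.get("differential_expression", {}).items():
        for biotype, c in entry.items():
            lines.append(
                f"{tp:>6} {biotype:>6}: {c['n_total']} deregulated "
                f"({c['n_up']} up, {c['n_down']} down)")
    if "overlap" in report:
        ov = report["overlap"]
        lines.append(f"overlap between timepoints: {ov['n_overlap']} "
                     f"lncRNAs ({ov['n_up']} up, {ov['n_down']} down in the "
                     "later timepoint)")
    for tp, a in report.get("annotation", {}).items():
        c = a["argmax_counts"]
        lines.append(
            f"{tp:>6}: most deregulated lncRNAs on chromosome "
            f"{a['argmax_chromosome']} ({c['n_up']} up = {c['pct_up']}% of "
            f"{a['total_up']}; {c['n_down']} down = {c['pct_down']}% of "
            f"{a['total_down']})")
    for tp, n in report.get("network", {}).items():
        if "hubs" in n:
            hubs = ", ".join(f"{h['id']}({h['degree']})" for h in n["hubs"])
            lines.append(f"{tp:>6}: {n['n_edges']} edges; top hubs: {hubs}; "
                         f"{n['n_distinct_mrna_partners']} distinct mRNA "
                         "partners")
        else:
            lines.append(f"{tp:>6}: {n['n_edges']} edges")
    for tp, e in report.get("enrichment", {}).items():
        lines.append(f"{tp:>6}: {e['n_significant_terms']} significant "
                     f"terms in {len(e.get('groups', []))} kappa groups")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# verification against planted truth

def verify_report(result: PipelineResult, truth: PlantedTruth) -> dict:
    """Scorecard of recovery rates against the planted ground truth.

    Sensitivity = called & planted / planted; FDP = called & not planted /
    called (per timepoint and biotype). Hub recovery = |top-k ∩ planted
    hubs| / planted hubs; term recovery likewise over planted enriched
    terms. A near-empty hub network is flagged unstable.
    """
    report = result.report
    de_section = report.get("differential_expression", {})
    ids_known = set(result.study.transcripts)
    for tp in de_section:
        if tp not in truth.de_lnc:
            raise ValueError(f"truth lacks timepoint {tp!r}")
    if missing := set(truth.de_lnc) - set(de_section):
        raise ValueError(f"report lacks timepoints {sorted(missing)}")

    card: dict = {"de": {}}
    for tp, entry in de_section.items():
        card["de"][tp] = {}
        for biotype in (LNCRNA, MRNA):
            called = set(entry[biotype]["called_ids"])
            if not called <= ids_known:
                raise ValueError("called ids missing from the study")
            planted = truth.de_ids(tp, biotype)
            tp_hit = len(called & planted)
            sens = tp_hit / len(planted) if planted else float("nan")
            fdp = ((len(called) - tp_hit) / len(called)
                   if called else float("nan"))
            card["de"][tp][biotype] = {"sensitivity": sens, "fdp": fdp,
                                       "n_called": len(called),
                                       "n_planted": len(planted)}

    dcm = truth.dcm_timepoint
    net = report.get("network", {}).get(dcm, {})
    hubs = [h["id"] for h in net.get("hubs", [])]
    planted_hubs = set(truth.hub_ids)
    if planted_hubs:
        card["hub_recovery"] = len(set(hubs) & planted_hubs) / len(planted_hubs)
    degrees = [h["degree"] for h in net.get("hubs", [])]
    card["hub_network_unstable"] = (not degrees) or max(degrees) < 3

    planted_terms = {t for terms in truth.enriched_terms.values()
                     for t in terms}
    if planted_terms:
        sig = set(report.get("enrichment", {}).get(dcm, {})
                  .get("significant_terms", []))
        card["term_recovery"] = len(sig & planted_terms) / len(planted_terms)
    return card
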