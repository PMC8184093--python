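"""End-to-end pipeline: parse → profile → topic evolution → gene ranking.

One configuration object drives every stage and a single run directory
collects the outputs: the monthly trend, top-N rankings, the co-term and
co-institution networks with communities, the topic lineage graph with its
statistics, the entity-cleaning report, the category edge tallies, top
entity tables, and the gene profile / emerging-gene list. A manifest
records the configuration, seed, package version and a content hash per
output so reruns can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import bioentity as be
from . import cooccur, corpus as cp, sep
from .synthetic import SYNTH_COUNTRIES, fixture_path

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    medline_path: str
    pubtator_path: str
    output_dir: str
    mesh_dict: str = ""
    gene_dict: str = ""
    snp_dict: str = ""
    granularity: str = "month"
    sigma: float = 0.1
    k_max: int = 10
    seed: int = 0
    min_df: int = 5
    ngram_max: int = 2
    resolution: float = 1.0
    top_n: int = 20
    cutoff: tuple[int, int] | None = None
    target_disease: str = "D000086382"
    ir_threshold: float = 0.5
    cc_threshold: float = 0.5
    top_k_highlighted: int = 4
    entropy_mode: str = "standard"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.min_df < 1 or self.k_max < 1 or self.top_n < 1:
            raise ValueError("min_df, k_max and top_n must be >= 1")
        if not (0 < self.ir_threshold < 1 and 0 < self.cc_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.entropy_mode not in ("standard", "literal"):
            raise ValueError("entropy_mode must be 'standard' or 'literal'")
        if self.granularity not in ("month", "year"):
            raise ValueError("granularity must be 'month' or 'year'")
        if not self.mesh_dict:
            self.mesh_dict = str(fixture_path("mesh_descriptors.tsv"))
        if not self.gene_dict:
            self.gene_dict = str(fixture_path("human_genes.tsv"))
        if not self.snp_dict:
            self.snp_dict = str(fixture_path("snp_variants.tsv"))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(data.get("cutoff"), list):
            data["cutoff"] = tuple(data["cutoff"])
        return cls(**data)

    def validate_inputs(self) -> None:
        for label, p in [("medline_path", self.medline_path),
                         ("pubtator_path", self.pubtator_path),
                         ("mesh_dict", self.mesh_dict),
                         ("gene_dict", self.gene_dict),
                         ("snp_dict", self.snp_dict)]:
            if not Path(p).is_file():
                raise PipelineError(f"config: missing input {label}={p!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest.

    Inputs are validated before anything is written, so a bad path leaves
    no partial outputs. Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    config.validate_inputs()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("parse")
        corpus = cp.parse_medline(config.medline_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage parse failed: {exc}") from exc

    try:
        stage("trend")
        cutoff = config.cutoff
        if cutoff is None:
            dated = [(r.pub_year, r.pub_month) for r in corpus
                     if r.pub_year is not None and r.pub_month is not None]
            if not dated:
                raise ValueError("no dated records for the trend")
            cutoff = max(dated)
        series, excluded = cp.monthly_trend(corpus, cutoff)
        outputs["trend"] = out / "monthly_trend.csv"
        cp.write_trend_csv(series, excluded, outputs["trend"])

        journals = cp.journal_frequencies(corpus)
        cleaner = cp.AffiliationCleaner(
            alias_table={}, country_gazetteer={c: c for c in SYNTH_COUNTRIES})
        inst_freq, country_freq = {}, {}
        for rec in corpus:
            seen_inst, seen_country = set(), set()
            for inst, country in cleaner.clean_record(rec):
                if inst:
                    seen_inst.add(inst)
                if country:
                    seen_country.add(country)
            for i in seen_inst:
                inst_freq[i] = inst_freq.get(i, 0) + 1
            for c in seen_country:
                country_freq[c] = country_freq.get(c, 0) + 1
        for label, freq in [("journals", journals),
                            ("institutions", inst_freq),
                            ("countries", country_freq)]:
            outputs[f"top_{label}"] = out / f"top_{label}.csv"
            ranked = cp.top_n(freq, config.top_n) if freq else []
            cp.write_top_n_csv(ranked, label[:-1], outputs[f"top_{label}"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage trend failed: {exc}") from exc

    try:
        stage("coterm")
        vocab, doc_terms = cp.extract_terms(
            corpus, min_df=config.min_df, ngram_max=config.ngram_max)
        coterm = cooccur.build_network(doc_terms)  # raw CF weights for terms
        if coterm.n_nodes:
            cooccur.detect_communities(coterm, resolution=config.resolution,
                                       seed=config.seed)
        outputs["coterm"] = out / "coterm.graphml"
        cooccur.export_graph(coterm, outputs["coterm"], "graphml")
    except Exception as exc:
        raise PipelineError(f"stage coterm failed: {exc}") from exc

    try:
        stage("coauthor")
        doc_insts = []
        for rec in corpus:
            insts = {inst for inst, _ in cleaner.clean_record(rec) if inst}
            doc_insts.append(insts)
        coauthor = cooccur.jaccard_normalize(cooccur.build_network(doc_insts))
        if coauthor.n_nodes:
            cooccur.detect_communities(coauthor, resolution=config.resolution,
                                       seed=config.seed)
        outputs["coauthor"] = out / "coauthor.graphml"
        cooccur.export_graph(coauthor, outputs["coauthor"], "graphml")
    except Exception as exc:
        raise PipelineError(f"stage coauthor failed: {exc}") from exc

    try:
        stage("sep")
        stream = sep.prepare_stream(corpus, vocab,
                                    granularity=config.granularity,
                                    cutoff=config.cutoff)
        graph = sep.run_sep(stream, sigma=config.sigma, k_max=config.k_max,
                            seed=config.seed)
        outputs["sep_graph"] = out / "sep.graphml"
        sep.export_sep_graphml(graph, outputs["sep_graph"])
        outputs["sep_membership"] = out / "sep_membership.csv"
        sep.write_membership_csv(graph, outputs["sep_membership"])
        outputs["sep_stats"] = out / "sep_statistics.json"
        outputs["sep_stats"].write_text(
            json.dumps(sep.sep_statistics(graph), indent=2), encoding="utf-8")
    except Exception as exc:
        raise PipelineError(f"stage sep failed: {exc}") from exc

    try:
        stage("bioentity")
        mentions = be.read_pubtator(config.pubtator_path)
        doc_entities, report = be.resolve_mentions(
            mentions,
            be.load_mesh_dict(config.mesh_dict),
            be.load_gene_dict(config.gene_dict),
            be.load_snp_dict(config.snp_dict))
        outputs["cleaning_report"] = out / "cleaning_report.csv"
        report.write_csv(outputs["cleaning_report"])
        net = be.build_hetero_network(doc_entities)
        outputs["hetero_graph"] = out / "bioentity.graphml"
        be.export_hetero_graphml(net, outputs["hetero_graph"])
        outputs["edge_tallies"] = out / "edge_tallies.csv"
        be.category_pair_edge_counts(net).to_csv(outputs["edge_tallies"],
                                                 index_label="category")
        for cat in be.CATEGORIES:
            top, series = be.entity_frequency_trend(
                mentions, corpus, top_k=10, category=cat)
            path = out / f"top_entities_{cat}.csv"
            outputs[f"top_entities_{cat}"] = path
            with open(path, "w", encoding="utf-8", newline="") as handle:
                handle.write("rank,entity_id,name,raw_frequency\n")
                for i, (e, c) in enumerate(top, 1):
                    handle.write(f"{i},{e.entity_id},{e.name},{c}\n")
            series.to_csv(out / f"trend_entities_{cat}.csv",
                          index_label="month")
    except Exception as exc:
        raise PipelineError(f"stage bioentity failed: {exc}") from exc

    try:
        stage("rank-genes")
        profiles, weights = be.compute_gene_profiles(
            net, target_disease=config.target_disease,
            entropy_mode=config.entropy_mode)
        emerging, highlighted = be.emerging_map(
            profiles, ir_threshold=config.ir_threshold,
            cc_threshold=config.cc_threshold,
            top_k_highlighted=config.top_k_highlighted)
        outputs["gene_profiles"] = out / "gene_profiles.csv"
        be.write_gene_profiles_csv(profiles, outputs["gene_profiles"])
        outputs["emerging_genes"] = out / "emerging_genes.csv"
        with open(outputs["emerging_genes"], "w", encoding="utf-8",
                  newline="") as handle:
            handle.write("rank,gene_id,symbol,ir_norm,combined_norm\n")
            for i, p in enumerate(emerging, 1):
                handle.write(f"{i},{p.entity.entity_id},{p.entity.name},"
                             f"{p.ir_norm:.6f},{p.combined_norm:.6f}\n")
        outputs["highlighted_genes"] = out / "highlighted_genes.csv"
        with open(outputs["highlighted_genes"], "w", encoding="utf-8",
                  newline="") as handle:
            handle.write("rank,gene_id,symbol,combined\n")
            for i, p in enumerate(highlighted, 1):
                handle.write(f"{i},{p.entity.entity_id},{p.entity.name},"
                             f"{p.combined:.6f}\n")
    except Exception as exc:
        raise PipelineError(f"stage rank-genes failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "entropy_weights": {"dc": weights[0], "cc": weights[1],
                            "bc": weights[2]},
        "outputs": {name: {"path": p.name, "sha256": _sha256(p)}
                    for name, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")
    return manifest
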