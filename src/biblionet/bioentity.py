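"""Heterogeneous bio-entity network analysis for gene prioritization.

Builds a co-occurrence network over four entity categories — diseases,
chemicals, genes and genetic variants — from PubTator-style literature
annotations, then profiles each gene by two indicators:

* **Centrality combination** — an entropy-weighted sum of min-max
  normalized degree, closeness and betweenness centralities, proxying the
  breadth of a gene's influence across the literature network. The weight
  of each centrality is w = (1 - H) / (3 - ΣH), where H is the Shannon
  entropy of that centrality's distribution over nodes: a centrality whose
  values barely discriminate between nodes (high entropy) earns a small
  weight.
* **Intersection ratio (IR)** — the fraction of a gene's disease-edge
  weight pointing at the target disease, proxying disease specificity.

Plotting genes on the normalized (IR, combined-centrality) plane splits
them into quadrants; quadrant I (high on both axes) minus the
long-established top-centrality genes is the *emerging gene* list.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .corpus import Corpus

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "BioEntity",
    "Mention",
    "HeteroNetwork",
    "GeneProfile",
    "CleaningReport",
    "read_pubtator",
    "load_mesh_dict",
    "load_gene_dict",
    "load_snp_dict",
    "resolve_mentions",
    "build_hetero_network",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "all_centralities",
    "min_max_normalize",
    "entropy_weights",
    "combine_centralities",
    "intersection_ratio",
    "compute_gene_profiles",
    "emerging_map",
    "entity_frequency_trend",
    "category_pair_edge_counts",
]

CATEGORIES = ("disease", "chemical", "gene", "variant")

#: PubTator annotation types mapped onto the four analysis categories.
_TYPE_MAP = {
    "Disease": "disease",
    "Chemical": "chemical",
    "Gene": "gene",
    "Mutation": "variant",
    "SNP": "variant",
    "DNAMutation": "variant",
    "ProteinMutation": "variant",
}

HUMAN_TAX_ID = "9606"


@dataclass(frozen=True)
class BioEntity:
    """A resolved biomedical concept with a canonical identifier."""

    entity_id: str
    name: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category: {self.category!r}")
        if self.category == "variant" and not self.entity_id.startswith("rs"):
            raise ValueError("variant entities must carry rsIDs")


@dataclass
class Mention:
    """One annotation line: a surface form tagged in one document."""

    pmid: str
    text: str
    category: str
    raw_id: str
    entity: BioEntity | None = None


@dataclass
class GeneProfile:
    """Per-gene indicator bundle for the emerging-gene map."""

    entity: BioEntity
    dc: float
    cc: float
    bc: float
    ndc: float = 0.0
    ncc: float = 0.0
    nbc: float = 0.0
    combined: float = 0.0
    ir: float = 0.0
    ir_flag: bool = False  # True when the gene has no disease edges at all
    ir_norm: float = 0.0
    combined_norm: float = 0.0
    quadrant: str = ""


HeteroNetwork = nx.Graph  # typed co-occurrence graph; see build_hetero_network


# ---------------------------------------------------------------------------
# PubTator input and dictionary fixtures
# ---------------------------------------------------------------------------


def read_pubtator(source: str | Path | IO[str]) -> list[Mention]:
    """Parse PubTator raw format into mentions.

    The format alternates ``PMID|t|title`` / ``PMID|a|abstract`` lines with
    tab-delimited annotation lines (pmid, start, end, text, type, id).
    Annotation types outside the four analysis categories (e.g. Species)
    are dropped with a logged count; malformed lines are skipped.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return read_pubtator(handle)
    mentions: list[Mention] = []
    n_dropped = n_malformed = 0
    for line in source:
        line = line.rstrip("\n")
        if not line or "|t|" in line[:30] or "|a|" in line[:30]:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            n_malformed += 1
            logger.warning("skipping malformed PubTator line: %r", line[:80])
            continue
        pmid, start, end, text, ann_type, raw_id = fields[:6]
        if not (pmid and start.isdigit() and end.isdigit()):
            n_malformed += 1
            logger.warning("skipping malformed PubTator line: %r", line[:80])
            continue
        category = _TYPE_MAP.get(ann_type)
        if category is None:
            n_dropped += 1
            continue
        mentions.append(Mention(pmid=pmid, text=text, category=category,
                                raw_id=raw_id))
    if n_dropped or n_malformed:
        logger.info("read_pubtator: kept %d mentions, dropped %d "
                    "out-of-scope types, skipped %d malformed lines",
                    len(mentions), n_dropped, n_malformed)
    return mentions


def _read_tsv(path: str | Path) -> Iterable[list[str]]:
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


def load_mesh_dict(path: str | Path) -> dict[str, str]:
    """MeSH descriptor fixture: ``mesh_id <TAB> name`` → {id: name}."""
    return {row[0]: row[1] for row in _read_tsv(path)}


def load_gene_dict(path: str | Path,
                   tax_id: str = HUMAN_TAX_ID) -> dict[str, str]:
    """Gene fixture: ``gene_id <TAB> symbol <TAB> tax_id``.

    Only entries for the requested taxon (human by default) are retained,
    implementing the non-human-gene exclusion.
    """
    return {row[0]: row[1] for row in _read_tsv(path) if row[2] == tax_id}


def load_snp_dict(path: str | Path) -> dict[str, str]:
    """Variant fixture: ``rsID <TAB> alias`` (alias column optional).

    Returns a mapping from every known surface identifier (the rsID itself
    plus any mutation-notation alias) to the canonical rsID.
    """
    mapping: dict[str, str] = {}
    for row in _read_tsv(path):
        rsid = row[0]
        mapping[rsid] = rsid
        for alias in row[1:]:
            if alias:
                mapping[alias] = rsid
    return mapping


# ---------------------------------------------------------------------------
# Mention resolution (Table-3-style cleaning)
# ---------------------------------------------------------------------------


@dataclass
class CleaningReport:
    """Raw → cleaned → unique mention tallies per category."""

    raw: Counter = field(default_factory=Counter)
    cleaned: Counter = field(default_factory=Counter)
    unique: Counter = field(default_factory=Counter)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw_mentions": [self.raw[c] for c in CATEGORIES],
             "cleaned_mentions": [self.cleaned[c] for c in CATEGORIES],
             "unique_entities": [self.unique[c] for c in CATEGORIES]},
            index=list(CATEGORIES))

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="category")


def resolve_mentions(
    mentions: Sequence[Mention],
    mesh_dict: Mapping[str, str],
    gene_dict: Mapping[str, str],
    snp_dict: Mapping[str, str],
) -> tuple[dict[str, set[BioEntity]], CleaningReport]:
    """Map raw mentions to canonical bio-entities, dropping the unmappable.

    Diseases and chemicals must map to a MeSH entry; genes must be in the
    human gene dictionary; mutation mentions must map to an rsID (merging
    DNA/protein notation with explicit SNP mentions under one variant).
    Unresolved mentions are counted, never fatal. Returns per-document
    entity sets plus the cleaning tallies.
    """
    report = CleaningReport()
    doc_entities: dict[str, set[BioEntity]] = defaultdict(set)
    for m in mentions:
        report.raw[m.category] += 1
        entity = None
        if m.category in ("disease", "chemical"):
            name = mesh_dict.get(m.raw_id)
            if name is not None:
                entity = BioEntity(m.raw_id, name, m.category)
        elif m.category == "gene":
            symbol = gene_dict.get(m.raw_id)
            if symbol is not None:
                entity = BioEntity(m.raw_id, symbol, "gene")
        else:  # variant
            rsid = snp_dict.get(m.raw_id) or snp_dict.get(m.text)
            if rsid is not None:
                entity = BioEntity(rsid, rsid, "variant")
        if entity is not None:
            m.entity = entity
            report.cleaned[m.category] += 1
            doc_entities[m.pmid].add(entity)
    uniq: dict[str, set[str]] = defaultdict(set)
    for ents in doc_entities.values():
        for e in ents:
            uniq[e.category].add(e.entity_id)
    for cat in CATEGORIES:
        report.unique[cat] = len(uniq[cat])
    return dict(doc_entities), report


# ---------------------------------------------------------------------------
# Network construction and centralities
# ---------------------------------------------------------------------------


def build_hetero_network(
    doc_entity_sets: Mapping[str, Iterable[BioEntity]] | Iterable[Iterable[BioEntity]],
) -> HeteroNetwork:
    """Heterogeneous co-occurrence network over resolved entities.

    Edge weight = number of documents in which the two entities co-occur;
    intra- and inter-category edges are both kept. Entities never
    co-mentioned remain as isolated nodes.
    """
    if isinstance(doc_entity_sets, Mapping):
        doc_entity_sets = doc_entity_sets.values()
    g = nx.Graph()
    for entities in doc_entity_sets:
        uniq = sorted(set(entities), key=lambda e: (e.category, e.entity_id))
        for e in uniq:
            if not g.has_node(e.entity_id):
                g.add_node(e.entity_id, name=e.name, category=e.category)
        for a, b in _pairs(uniq):
            if g.has_edge(a.entity_id, b.entity_id):
                g.edges[a.entity_id, b.entity_id]["weight"] += 1
            else:
                g.add_edge(a.entity_id, b.entity_id, weight=1)
    return g


def _pairs(seq: Sequence):
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            yield seq[i], seq[j]


def degree_centrality(net: HeteroNetwork, v: str | None = None):
    """Fraction of other nodes adjacent to v (weights ignored)."""
    if net.number_of_nodes() < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    dc = nx.degree_centrality(net)
    return dc if v is None else dc[v]


def closeness_centrality(net: HeteroNetwork, v: str | None = None):
    """Closeness over unweighted hop distances.

    Uses the Wasserman–Faust correction
    (reachable/(n-1)) * (reachable/Σd), which equals the classical
    (n-1)/Σd on connected networks; isolated nodes score 0.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("closeness centrality needs at least 2 nodes")
    cc = nx.closeness_centrality(net, wf_improved=True)
    return cc if v is None else cc[v]


def betweenness_centrality(net: HeteroNetwork, v: str | None = None):
    """Shortest-path betweenness, normalized by (n-1)(n-2)/2."""
    if net.number_of_nodes() < 3:
        raise ValueError("betweenness centrality needs at least 3 nodes")
    bc = nx.betweenness_centrality(net, normalized=True, weight=None)
    return bc if v is None else bc[v]


def all_centralities(net: HeteroNetwork) -> pd.DataFrame:
    """DC, CC, BC for every node, as a DataFrame indexed by entity id."""
    nodes = sorted(net.nodes)
    return pd.DataFrame({
        "dc": pd.Series(degree_centrality(net)),
        "cc": pd.Series(closeness_centrality(net)),
        "bc": pd.Series(betweenness_centrality(net)),
    }).loc[nodes]


# ---------------------------------------------------------------------------
# Entropy-weight combination
# ---------------------------------------------------------------------------


def min_max_normalize(values: Sequence[float]) -> list[float] | None:
    """(x - min)/(max - min); ``None`` when the set is constant."""
    lo, hi = min(values), max(values)
    if hi == lo:
        return None
    return [(x - lo) / (hi - lo) for x in values]


def _entropy_standard(normalized: Sequence[float]) -> float:
    """Shannon entropy of the proportion distribution p_i = n_i / Σn.

    0·ln0 is taken as 0; the 1/ln(m) factor scales the result into [0, 1].
    """
    total = sum(normalized)
    if total == 0:
        return 1.0
    m = len(normalized)
    props = (x / total for x in normalized)
    h = -sum(p * math.log(p) for p in props if p > 0)
    return h / math.log(m)


def _entropy_literal(normalized: Sequence[float]) -> float:
    """Entropy evaluated on the min-max values directly, as printed.

    Because min-max values need not sum to 1 this can exceed 1, making
    1 - H negative; kept for comparison with the published formula.
    """
    m = len(normalized)
    return -sum(x * math.log(x) for x in normalized if x > 0) / math.log(m)


def entropy_weights(
    ndc: Sequence[float] | None,
    ncc: Sequence[float] | None,
    nbc: Sequence[float] | None,
    mode: str = "standard",
) -> tuple[float, float, float]:
    """Data-driven weights for the three centralities.

    Each argument is the min-max-normalized value set of one centrality
    (``None`` for a degenerate, constant centrality). Weight of centrality
    X is (1 - H_X) / (3 - ΣH); a degenerate centrality carries no ranking
    information and receives weight 0, with the remaining weights
    renormalized to sum to 1. In the default ``standard`` mode the
    normalized values are converted to proportions before the entropy; the
    ``literal`` mode applies the entropy to the min-max values directly.
    """
    if mode not in ("standard", "literal"):
        raise ValueError("mode must be 'standard' or 'literal'")
    ent = _entropy_standard if mode == "standard" else _entropy_literal
    sets = [ndc, ncc, nbc]
    hs: list[float | None] = [ent(s) if s is not None else None for s in sets]
    live = [h for h in hs if h is not None]
    if not live:
        logger.warning("all three centralities degenerate; equal weights")
        return (1 / 3, 1 / 3, 1 / 3)
    denom = len(live) - sum(live)
    if denom == 0:
        # all live entropies exactly 1: no discrimination anywhere
        w = [0.0 if h is None else 1 / len(live) for h in hs]
    else:
        w = [0.0 if h is None else (1 - h) / denom for h in hs]
    total = sum(w)
    w = [x / total for x in w]
    if any(h is None for h in hs):
        logger.info("degenerate centrality received weight 0; "
                    "remaining weights renormalized to %s", w)
    return tuple(w)  # type: ignore[return-value]


def combine_centralities(
    normalized: Mapping[str, tuple[float, float, float]],
    weights: tuple[float, float, float],
) -> dict[str, float]:
    """Weighted sum w_DC·nDC + w_CC·nCC + w_BC·nBC per node."""
    if not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
        raise ValueError("weights must sum to 1")
    return {node: sum(w * x for w, x in zip(weights, triple))
            for node, triple in normalized.items()}


# ---------------------------------------------------------------------------
# Intersection ratio and the emerging-gene map
# ---------------------------------------------------------------------------


def intersection_ratio(net: HeteroNetwork, v: str,
                       target_disease: str) -> tuple[float, bool]:
    """Share of v's disease-edge weight pointing at the target disease.

    Returns ``(ir, flag)`` where the flag marks nodes with no disease
    edges at all (their IR is reported as 0).
    """
    if target_disease not in net:
        raise KeyError(f"target disease {target_disease!r} not in network")
    if net.nodes[target_disease]["category"] != "disease":
        raise ValueError(f"{target_disease!r} is not a disease node")
    if v not in net:
        raise KeyError(f"unknown entity: {v!r}")
    disease_weight = 0.0
    target_weight = 0.0
    for _, nbr, data in net.edges(v, data=True):
        if net.nodes[nbr]["category"] == "disease":
            disease_weight += data["weight"]
            if nbr == target_disease:
                target_weight = data["weight"]
    if disease_weight == 0:
        return 0.0, True
    return target_weight / disease_weight, False


def compute_gene_profiles(
    net: HeteroNetwork,
    target_disease: str,
    entropy_mode: str = "standard",
) -> tuple[list[GeneProfile], tuple[float, float, float]]:
    """Centrality combination and IR for every gene in the network.

    Centralities are computed on the unweighted skeleton of the whole
    heterogeneous network and min-max normalized over **all** nodes (the
    entropy weighting sees the full network); IR uses the disease-edge
    weights. Returns gene profiles plus the entropy weights used.
    """
    cents = all_centralities(net)
    norms = {}
    for col in ("dc", "cc", "bc"):
        norms[col] = min_max_normalize(list(cents[col]))
    weights = entropy_weights(norms["dc"], norms["cc"], norms["bc"],
                              mode=entropy_mode)
    nodes = list(cents.index)
    triples = {
        node: tuple(
            (norms[col][i] if norms[col] is not None else 0.0)
            for col in ("dc", "cc", "bc"))
        for i, node in enumerate(nodes)
    }
    combined = combine_centralities(triples, weights)
    profiles = []
    for node in nodes:
        if net.nodes[node]["category"] != "gene":
            continue
        ir, flag = intersection_ratio(net, node, target_disease)
        ndc, ncc, nbc = triples[node]
        profiles.append(GeneProfile(
            entity=BioEntity(node, net.nodes[node]["name"], "gene"),
            dc=float(cents.loc[node, "dc"]), cc=float(cents.loc[node, "cc"]),
            bc=float(cents.loc[node, "bc"]),
            ndc=ndc, ncc=ncc, nbc=nbc,
            combined=combined[node], ir=ir, ir_flag=flag))
    return profiles, weights


def emerging_map(
    profiles: Sequence[GeneProfile],
    ir_threshold: float = 0.5,
    cc_threshold: float = 0.5,
    top_k_highlighted: int = 4,
) -> tuple[list[GeneProfile], list[GeneProfile]]:
    """Quadrant classification of genes on the normalized indicator plane.

    Both axes (IR on x, centrality combination on y) are min-max
    normalized over the genes. Quadrant I holds genes above both
    thresholds; the *highlighted* set is the top-k genes by combined
    centrality (the long-established players) and the *emerging* list is
    quadrant I minus the highlighted set, ranked by normalized IR then
    combined centrality. Mutates ``profiles`` in place (normalized axes,
    quadrant) and returns (emerging, highlighted).
    """
    if len(profiles) < 2:
        raise ValueError("emerging map needs at least 2 genes")
    if not (0 < ir_threshold < 1 and 0 < cc_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    ir_norm = min_max_normalize([p.ir for p in profiles])
    cn_norm = min_max_normalize([p.combined for p in profiles])
    for i, p in enumerate(profiles):
        p.ir_norm = ir_norm[i] if ir_norm is not None else 0.0
        p.combined_norm = cn_norm[i] if cn_norm is not None else 0.0
        hi_ir = p.ir_norm > ir_threshold
        hi_cc = p.combined_norm > cc_threshold
        p.quadrant = ("I" if hi_ir and hi_cc else
                      "II" if hi_cc else
                      "IV" if hi_ir else "III")
    highlighted = sorted(
        profiles, key=lambda p: (-p.combined, p.entity.entity_id),
    )[:top_k_highlighted]
    highlighted_ids = {p.entity.entity_id for p in highlighted}
    emerging = sorted(
        (p for p in profiles
         if p.quadrant == "I" and p.entity.entity_id not in highlighted_ids),
        key=lambda p: (-p.ir_norm, -p.combined_norm, p.entity.entity_id))
    return emerging, highlighted


def write_gene_profiles_csv(profiles: Sequence[GeneProfile],
                            path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        w = csv.writer(handle)
        w.writerow(["gene_id", "symbol", "dc", "cc", "bc",
                    "combined", "ir", "ir_norm", "combined_norm",
                    "quadrant", "no_disease_edges"])
        for p in sorted(profiles, key=lambda p: p.entity.entity_id):
            w.writerow([p.entity.entity_id, p.entity.name,
                        f"{p.dc:.6f}", f"{p.cc:.6f}", f"{p.bc:.6f}",
                        f"{p.combined:.6f}", f"{p.ir:.6f}",
                        f"{p.ir_norm:.6f}", f"{p.combined_norm:.6f}",
                        p.quadrant, int(p.ir_flag)])


# ---------------------------------------------------------------------------
# Frequency reporting (Table-4/5 and Fig-6 shapes)
# ---------------------------------------------------------------------------


def category_pair_edge_counts(net: HeteroNetwork) -> pd.DataFrame:
    """4x4 table of edge counts per category pair.

    Each unordered edge is counted once: it lands in cell (cat_i, cat_j)
    with the categories in canonical order, so the table is upper-
    triangular-plus-diagonal and its total equals the edge count.
    """
    order = {c: k for k, c in enumerate(CATEGORIES)}
    table = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for a, b in net.edges:
        ca, cb = net.nodes[a]["category"], net.nodes[b]["category"]
        if order[ca] > order[cb]:
            ca, cb = cb, ca
        table.loc[ca, cb] += 1
    return table


def entity_frequency_trend(
    mentions: Sequence[Mention],
    corpus: Corpus,
    top_k: int = 10,
    category: str | None = None,
    by: str = "mentions",
) -> tuple[list[tuple[BioEntity, int]], pd.DataFrame]:
    """Top entities by raw frequency plus their monthly mention series.

    ``by='mentions'`` counts every mention (the raw-frequency convention);
    ``by='documents'`` counts distinct documents instead. The monthly
    series covers the corpus date range; mentions in undated records are
    excluded from the series but still count toward the totals.
    """
    if by not in ("mentions", "documents"):
        raise ValueError("by must be 'mentions' or 'documents'")
    resolved = [m for m in mentions if m.entity is not None
                and (category is None or m.entity.category == category)]
    if by == "mentions":
        totals = Counter(m.entity for m in resolved)
    else:
        totals = Counter({e: len(ps) for e, ps in
                          _entity_docs(resolved).items()})
    top = sorted(totals.items(),
                 key=lambda kv: (-kv[1], kv[0].entity_id))[:top_k]
    dates = {r.pmid: (r.pub_year, r.pub_month) for r in corpus
             if r.pub_year is not None and r.pub_month is not None}
    rows: dict[tuple[int, int], Counter] = defaultdict(Counter)
    top_entities = {e for e, _ in top}
    for m in resolved:
        if m.entity in top_entities and m.pmid in dates:
            rows[dates[m.pmid]][m.entity.name] += 1
    if rows:
        months = sorted(rows)
        frame = pd.DataFrame(
            [[rows[ym].get(e.name, 0) for e, _ in top] for ym in months],
            index=[f"{y}-{m:02d}" for y, m in months],
            columns=[e.name for e, _ in top])
    else:
        frame = pd.DataFrame(columns=[e.name for e, _ in top])
    return top, frame


def _entity_docs(mentions: Sequence[Mention]) -> dict[BioEntity, set[str]]:
    docs: dict[BioEntity, set[str]] = defaultdict(set)
    for m in mentions:
        docs[m.entity].add(m.pmid)
    return docs


def export_hetero_graphml(net: HeteroNetwork, path: str | Path) -> None:
    nx.write_graphml(net, path)
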