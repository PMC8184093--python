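"""Synthetic corpora with planted ground truth.

Three generators emulate the structures the analysis modules consume, so
the whole pipeline is testable without any download:

* a multi-slice document stream whose term distributions follow a planted
  topic birth schedule (for topic-evolution recovery),
* affiliation lists with planted collaboration communities (a
  planted-partition model over institutions),
* per-document bio-entity mention sets with a planted hub gene (broad
  co-mentions, highest expected centrality) and a planted target-specific
  gene (disease edges only to the target, expected IR = 1), written in
  PubTator raw format against the fixture dictionaries shipped with the
  package.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np

from .bioentity import load_gene_dict, load_mesh_dict, load_snp_dict
from .corpus import Corpus, PublicationRecord

__all__ = [
    "TopicSpec",
    "TopicPlan",
    "GroundTruth",
    "default_topic_plan",
    "generate_topic_stream",
    "generate_collaboration",
    "generate_bioentity_corpus",
    "fixture_path",
    "SYNTH_COUNTRIES",
]

#: Synthetic country gazetteer used by the collaboration generator.
SYNTH_COUNTRIES = [
    "Atlantis", "Borduria", "Carpathia", "Dorne", "Elbonia",
    "Freedonia", "Grandia", "Hyrulia",
]


def fixture_path(name: str) -> Path:
    """Path to a dictionary fixture shipped with the package."""
    return Path(resources.files("biblionet").joinpath("data", name))


@dataclass
class TopicSpec:
    """One planted topic: its vocabulary block and lifetime."""

    topic_id: str
    terms: list[str]
    birth_slice: int
    parent: str | None = None
    docs_per_slice: int = 50


@dataclass
class TopicPlan:
    """A planted topic birth/split schedule for a document stream."""

    topics: list[TopicSpec]
    n_slices: int
    noise: float = 0.1
    terms_per_doc: int = 12
    background_terms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise < 1:
            raise ValueError("noise rate must be in [0, 1)")
        by_id = {t.topic_id: t for t in self.topics}
        for t in self.topics:
            if t.birth_slice >= self.n_slices:
                raise ValueError(f"topic {t.topic_id} born after last slice")
            if t.parent is not None:
                parent = by_id.get(t.parent)
                if parent is None:
                    raise ValueError(f"unknown parent: {t.parent}")
                if parent.birth_slice > t.birth_slice:
                    raise ValueError("child born before its parent")


@dataclass
class GroundTruth:
    """Planted labels covering every generated document/entity."""

    doc_topic: dict[str, str] = field(default_factory=dict)
    lineage: list[tuple[str, str]] = field(default_factory=list)
    communities: dict[str, int] = field(default_factory=dict)
    hub_gene: str | None = None
    specific_gene: str | None = None
    target_disease: str | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2),
                              encoding="utf-8")


def _slice_date(slice_index: int, start=(2020, 1)) -> tuple[int, int]:
    y, m = start
    m0 = (m - 1) + slice_index
    return y + m0 // 12, m0 % 12 + 1


# ---------------------------------------------------------------------------
# Topic stream
# ---------------------------------------------------------------------------


def default_topic_plan(seed: int = 0) -> TopicPlan:
    """A four-topic birth/split schedule over six monthly slices.

    One root topic born at slice 0 and three descendants born at slices
    2, 3 and 4, each with a disjoint 12-term vocabulary block, 80 documents
    per active slice and a 10% off-block noise rate — roughly 1,200
    documents in total, small enough to stream in seconds.
    """
    def block(name: str) -> list[str]:
        return [f"{name}term{i:02d}x" for i in range(12)]

    topics = [
        TopicSpec("T0", block("alpha"), birth_slice=0, docs_per_slice=80),
        TopicSpec("T1", block("bravo"), birth_slice=2, parent="T0",
                  docs_per_slice=80),
        TopicSpec("T2", block("delta"), birth_slice=3, parent="T0",
                  docs_per_slice=80),
        TopicSpec("T3", block("golf"), birth_slice=4, parent="T1",
                  docs_per_slice=80),
    ]
    return TopicPlan(topics=topics, n_slices=6, noise=0.1, seed=seed)


def generate_topic_stream(plan: TopicPlan) -> tuple[Corpus, GroundTruth]:
    """Generate a dated corpus following a planted topic schedule.

    Each document draws ``terms_per_doc`` tokens: with probability
    1 - noise from its topic's vocabulary block, otherwise uniformly from
    the global vocabulary (all blocks plus background filler terms). Dates
    place each document in its plan slice (monthly from 2020-01).
    """
    rng = np.random.default_rng(plan.seed)
    global_vocab = sorted(
        {t for spec in plan.topics for t in spec.terms}
        | {f"fillerterm{i:02d}x" for i in range(plan.background_terms)})
    truth = GroundTruth(
        lineage=[(t.parent, t.topic_id) for t in plan.topics
                 if t.parent is not None])
    records = []
    pmid = 90000000
    for s in range(plan.n_slices):
        year, month = _slice_date(s)
        for spec in plan.topics:
            if spec.birth_slice > s:
                continue
            for _ in range(spec.docs_per_slice):
                pmid += 1
                tokens = []
                for _ in range(plan.terms_per_doc):
                    if rng.random() < plan.noise:
                        tokens.append(global_vocab[
                            rng.integers(len(global_vocab))])
                    else:
                        tokens.append(spec.terms[
                            rng.integers(len(spec.terms))])
                records.append(PublicationRecord(
                    pmid=str(pmid),
                    title=" ".join(tokens[:3]).capitalize(),
                    abstract=" ".join(tokens[3:]),
                    journal="Journal of Synthetic Streams",
                    pub_year=year, pub_month=month))
                truth.doc_topic[str(pmid)] = spec.topic_id
    return Corpus(records=records, provenance="synthetic-topic-stream"), truth


# ---------------------------------------------------------------------------
# Collaboration corpus (planted partition over institutions)
# ---------------------------------------------------------------------------


def generate_collaboration(
    n_institutions: int = 30,
    k_communities: int = 3,
    p_in: float = 0.9,
    p_out: float = 0.05,
    n_docs: int = 200,
    seed: int = 0,
) -> tuple[Corpus, GroundTruth]:
    """Planted-partition collaboration corpus.

    Institutions are split evenly into ``k_communities``. Each document
    anchors on one institution; every other institution joins the
    document's author list with probability ``p_in`` when it shares the
    anchor's community and ``p_out`` otherwise, so within-community pairs
    co-occur far more often than across-community pairs.
    """
    if not p_in > p_out:
        raise ValueError("planted partition requires p_in > p_out")
    rng = np.random.default_rng(seed)
    insts = [f"University of Synthtown {i:02d}" for i in range(n_institutions)]
    comm = {insts[i]: i % k_communities for i in range(n_institutions)}
    country = {insts[i]: SYNTH_COUNTRIES[comm[insts[i]] % len(SYNTH_COUNTRIES)]
               for i in range(n_institutions)}
    truth = GroundTruth(communities={i: c for i, c in comm.items()})
    records = []
    for d in range(n_docs):
        anchor = insts[int(rng.integers(n_institutions))]
        authors = [anchor]
        for other in insts:
            if other == anchor:
                continue
            p = p_in if comm[other] == comm[anchor] else p_out
            if rng.random() < p:
                authors.append(other)
        year, month = _slice_date(int(rng.integers(6)))
        records.append(PublicationRecord(
            pmid=str(80000000 + d),
            title=f"Collaborative genomic surveillance report {d}",
            abstract="A multi-center study of synthetic collaboration.",
            journal="Annals of Synthetic Collaboration",
            pub_year=year, pub_month=month,
            affiliations=[
                f"Department of Genomics, {a}, Synthtown, {country[a]}"
                for a in authors]))
    return Corpus(records=records,
                  provenance="synthetic-collaboration"), truth


# ---------------------------------------------------------------------------
# Bio-entity corpus (PubTator format with planted hub/specific genes)
# ---------------------------------------------------------------------------

_TARGET_DISEASE = "D000086382"  # the COVID-19 fixture entry


def generate_bioentity_corpus(
    n_docs: int = 300,
    hub_gene: str = "59272",       # ACE2 in the gene fixture
    specific_gene: str = "9636",   # ISG15 in the gene fixture
    target_disease: str = _TARGET_DISEASE,
    frac_specific: float = 0.15,
    frac_hub: float = 0.30,
    seed: int = 0,
) -> tuple[str, Corpus, GroundTruth]:
    """Generate a PubTator-format corpus with planted gene structure.

    Three document recipes:

    * *specific* documents (``frac_specific``) mention the specific gene,
      the target disease (never a distractor disease), chemicals and
      variants drawn from the *whole* pools — including peripheral
      chemicals and variants that no other recipe uses, so the specific
      gene is their only bridge into the network. Its intersection ratio
      is exactly 1 by construction while its centrality stays high: the
      profile of an emerging gene, broadly discussed but only in the
      target-disease context;
    * *hub* documents (``frac_hub``) mention the hub gene with the target
      disease, frequent distractor diseases, common chemicals, common
      variants and other genes — the hub accumulates the highest expected
      degree and closeness;
    * *background* documents mention one roster gene with one disease and
      occasional common chemicals/variants.

    Returns the PubTator text, a matching dated corpus, and the ground
    truth. The text round-trips through the PubTator reader and resolves
    against the shipped fixture dictionaries.
    """
    if hub_gene == specific_gene:
        raise ValueError("hub and specific gene must differ")
    rng = np.random.default_rng(seed)
    mesh = load_mesh_dict(fixture_path("mesh_descriptors.tsv"))
    genes = load_gene_dict(fixture_path("human_genes.tsv"))
    snps = sorted({v for v in load_snp_dict(
        fixture_path("snp_variants.tsv")).values()})
    diseases = [m for m in mesh if m in _DISEASE_IDS]
    chemicals = [m for m in mesh if m not in _DISEASE_IDS]
    common_chems = chemicals[:8]     # shared by all recipes
    common_snps_n = 6                # variants also used outside specific docs
    distractors = [d for d in diseases if d != target_disease]
    roster = sorted(g for g in genes if g not in (hub_gene, specific_gene))

    truth = GroundTruth(hub_gene=hub_gene, specific_gene=specific_gene,
                        target_disease=target_disease)
    lines: list[str] = []
    records: list[PublicationRecord] = []
    for d in range(n_docs):
        pmid = str(70000000 + d)
        u = rng.random()
        ents: list[tuple[str, str, str]] = []  # (category, id, name)

        def add(cat: str, eid: str, name: str) -> None:
            if not any(e[1] == eid for e in ents):
                ents.append((cat, eid, name))

        if u < frac_specific:
            add("gene", specific_gene, genes[specific_gene])
            add("disease", target_disease, mesh[target_disease])
            for c in rng.choice(chemicals, size=3, replace=False):
                add("chemical", str(c), mesh[str(c)])
            n_var = 1 if rng.random() < 0.5 else 2
            for _ in range(n_var):
                v = snps[int(rng.integers(len(snps)))]
                add("variant", v, v)
        elif u < frac_specific + frac_hub:
            add("gene", hub_gene, genes[hub_gene])
            add("disease", target_disease, mesh[target_disease])
            if rng.random() < 0.5:
                dd = distractors[int(rng.integers(len(distractors)))]
                add("disease", dd, mesh[dd])
            if rng.random() < 0.5:
                g = roster[int(rng.integers(len(roster)))]
                add("gene", g, genes[g])
            for c in rng.choice(common_chems, size=2, replace=False):
                add("chemical", str(c), mesh[str(c)])
            if rng.random() < 0.5:
                v = snps[int(rng.integers(common_snps_n))]
                add("variant", v, v)
        else:
            g = roster[int(rng.integers(len(roster)))]
            add("gene", g, genes[g])
            if rng.random() < 0.5:
                add("disease", target_disease, mesh[target_disease])
            else:
                dd = distractors[int(rng.integers(len(distractors)))]
                add("disease", dd, mesh[dd])
            if rng.random() < 0.6:
                c = common_chems[int(rng.integers(len(common_chems)))]
                add("chemical", c, mesh[c])
            if rng.random() < 0.15:
                v = snps[int(rng.integers(common_snps_n))]
                add("variant", v, v)

        title = f"Synthetic report {d} on {ents[0][2]}"
        abstract = ("We investigated " +
                    ", ".join(e[2] for e in ents) +
                    " in a simulated patient cohort.")
        full_text = title + " " + abstract
        lines.append(f"{pmid}|t|{title}")
        lines.append(f"{pmid}|a|{abstract}")
        for cat, eid, name in ents:
            start = full_text.find(name)
            end = start + len(name)
            ann_type = {"disease": "Disease", "chemical": "Chemical",
                        "gene": "Gene", "variant": "SNP"}[cat]
            lines.append(f"{pmid}\t{start}\t{end}\t{name}\t{ann_type}\t{eid}")
        # a Species annotation per document exercises out-of-scope dropping
        lines.append(f"{pmid}\t0\t9\tSynthetic\tSpecies\t9606")
        lines.append("")

        year, month = 2020, int(rng.integers(1, 13))
        records.append(PublicationRecord(
            pmid=pmid, title=title, abstract=abstract,
            journal="Journal of Synthetic Bio-Entities",
            pub_year=year, pub_month=month))
    pubtator_text = "\n".join(lines) + "\n"
    return pubtator_text, Corpus(
        records=records, provenance="synthetic-bioentity"), truth


#: MeSH ids in the fixture that denote diseases (the rest are chemicals).
_DISEASE_IDS = {
    "D000086382", "D007251", "D045169", "D018352", "D003920", "D006973",
    "D009765", "D001249", "D011014", "D009369", "D002318", "D013927",
    "D020521", "D007674", "D012128",
}
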