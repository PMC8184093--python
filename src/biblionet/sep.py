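"""Scientific Evolutionary Pathways: streaming topic-drift detection.

Documents are represented as L2-normalized term-frequency vectors and
streamed in chronological slices (monthly or yearly). The first slice
seeds a single topic; each later document is matched to its most similar
existing topic (Salton cosine) and declared *drifted* when its Euclidean
distance E to that topic's centroid exceeds the topic radius r by more
than a relative threshold:

    (E - r) / r > sigma        (sigma defaults to 0.1)

Drifted documents of a slice are clustered with K-means into new topics,
which become descendants of the topics that rejected them. The output is a
directed lineage graph of topics, each stamped with its birth slice.

Because vectors are unit-length, cosine and Euclidean orderings agree
(E^2 = 2 - 2*cos), so the nearest-by-cosine candidate is also the
nearest-by-distance one.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .corpus import Corpus, TermVocabulary, term_frequencies

logger = logging.getLogger(__name__)

__all__ = [
    "DocVector",
    "Topic",
    "SEPGraph",
    "DocStream",
    "prepare_stream",
    "init_topic",
    "drift_test",
    "update_topic",
    "spawn_topics",
    "run_sep",
    "sep_statistics",
    "export_sep_graphml",
    "write_membership_csv",
]

#: Radius below which a topic is treated as degenerate (all members
#: identical); any measurable departure from such a topic is a drift.
RADIUS_EPS = 1e-9


@dataclass
class DocVector:
    """One document as a unit-length term-frequency vector."""

    pmid: str
    slice_index: int
    vector: np.ndarray

    def __post_init__(self) -> None:
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")


@dataclass
class Topic:
    """A topic: member documents, their centroid, radius and label.

    The centroid is the arithmetic mean of member vectors; the radius is
    the largest Euclidean distance from the centroid to any member; the
    label is the most document-frequent term among members (ties broken
    lexicographically).
    """

    id: int
    label: str
    birth_slice: int
    centroid: np.ndarray
    radius: float
    members: list[str]
    member_vectors: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DocStream:
    """Chronologically sliced document vectors over a fixed vocabulary."""

    slices: list[list[DocVector]]
    terms: list[str]
    n_dropped: int = 0

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def n_docs(self) -> int:
        return sum(len(s) for s in self.slices)


@dataclass
class SEPGraph:
    """Topic set plus directed predecessor→descendant lineage edges."""

    topics: dict[int, Topic]
    edges: set[tuple[int, int]]
    assignment: dict[str, int]  # pmid -> topic id at termination

    def __post_init__(self) -> None:
        for parent, child in self.edges:
            if self.topics[parent].birth_slice > self.topics[child].birth_slice:
                raise ValueError("lineage edge goes backwards in time")

    @property
    def n_topics(self) -> int:
        return len(self.topics)


# ---------------------------------------------------------------------------
# Stream preparation
# ---------------------------------------------------------------------------


def prepare_stream(
    corpus: Corpus,
    vocabulary: TermVocabulary,
    granularity: str = "month",
    cutoff: tuple[int, int] | int | None = None,
) -> DocStream:
    """Vectorize and slice a corpus chronologically.

    Documents are term-frequency weighted over the vocabulary and
    L2-normalized. Slices are contiguous calendar months (or years) from
    the earliest usable date; records lacking the needed date fields, dated
    after ``cutoff``, or containing no vocabulary term are dropped with a
    logged count.
    """
    if granularity not in ("month", "year"):
        raise ValueError("granularity must be 'month' or 'year'")
    term_index = {t: i for i, t in enumerate(vocabulary.terms)}
    dated = []  # (period index, record)
    n_dropped = 0
    for rec in corpus:
        if rec.pub_year is None or (granularity == "month"
                                    and rec.pub_month is None):
            n_dropped += 1
            continue
        if granularity == "month":
            period = rec.pub_year * 12 + (rec.pub_month - 1)
            if cutoff is not None:
                cy, cm = cutoff
                if period > cy * 12 + (cm - 1):
                    n_dropped += 1
                    continue
        else:
            period = rec.pub_year
            if cutoff is not None:
                cy = cutoff[0] if isinstance(cutoff, tuple) else cutoff
                if period > cy:
                    n_dropped += 1
                    continue
        dated.append((period, rec))
    if not dated:
        raise ValueError("no records with usable dates for streaming")

    first = min(p for p, _ in dated)
    last = max(p for p, _ in dated)
    slices: list[list[DocVector]] = [[] for _ in range(last - first + 1)]
    for period, rec in dated:
        counts = term_frequencies(rec, vocabulary)
        if not counts:
            n_dropped += 1
            continue
        vec = np.zeros(len(term_index))
        for term, c in counts.items():
            vec[term_index[term]] = c
        vec /= np.linalg.norm(vec)
        slices[period - first].append(
            DocVector(pmid=rec.pmid, slice_index=period - first, vector=vec))
    if n_dropped:
        logger.info("prepare_stream: dropped %d records (undated, past "
                    "cutoff, or no vocabulary terms)", n_dropped)
    return DocStream(slices=slices, terms=list(vocabulary.terms),
                     n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Topic geometry
# ---------------------------------------------------------------------------


def _top_term(vectors: Sequence[np.ndarray], terms: Sequence[str]) -> str:
    """Most document-frequent term among members; lexicographic tie-break."""
    presence = np.zeros(len(terms), dtype=int)
    for v in vectors:
        presence += (v > 0).astype(int)
    best = presence.max()
    candidates = [terms[i] for i in np.flatnonzero(presence == best)]
    return min(candidates)


def _make_topic(topic_id: int, birth_slice: int, docs: Sequence[DocVector],
                terms: Sequence[str]) -> Topic:
    vectors = [d.vector for d in docs]
    centroid = np.mean(vectors, axis=0)
    radius = max(float(np.linalg.norm(v - centroid)) for v in vectors)
    return Topic(
        id=topic_id, label=_top_term(vectors, terms),
        birth_slice=birth_slice, centroid=centroid, radius=radius,
        members=[d.pmid for d in docs], member_vectors=list(vectors))


def init_topic(slice0: Sequence[DocVector], terms: Sequence[str]) -> Topic:
    """Group all first-slice documents into the single initial topic."""
    if not slice0:
        raise ValueError("slice 0 is empty; start the stream at a later "
                         "slice or widen the date range")
    return _make_topic(0, slice0[0].slice_index, slice0, terms)


def drift_test(doc: DocVector, topic: Topic, sigma: float = 0.1) -> str:
    """Classify a document against a topic: ``'assigned'`` or ``'drifted'``.

    Drifted iff (E - r)/r > sigma, with E the Euclidean distance from the
    document to the topic centroid. A zero-radius topic (singleton or
    identical members) makes the ratio undefined; there any distance above
    :data:`RADIUS_EPS` counts as drift.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    e = float(np.linalg.norm(doc.vector - topic.centroid))
    if topic.radius < RADIUS_EPS:
        return "drifted" if e > RADIUS_EPS else "assigned"
    return "drifted" if (e - topic.radius) / topic.radius > sigma else "assigned"


def update_topic(topic: Topic, new_members: Sequence[DocVector],
                 terms: Sequence[str]) -> Topic:
    """Fold newly assigned documents into a topic.

    Centroid, radius and label are recomputed over the full membership.
    Returns the same Topic object, mutated.
    """
    if not new_members:
        return topic
    topic.members.extend(d.pmid for d in new_members)
    topic.member_vectors.extend(d.vector for d in new_members)
    topic.centroid = np.mean(topic.member_vectors, axis=0)
    topic.radius = max(float(np.linalg.norm(v - topic.centroid))
                       for v in topic.member_vectors)
    topic.label = _top_term(topic.member_vectors, terms)
    return topic


# ---------------------------------------------------------------------------
# Spawning descendants
# ---------------------------------------------------------------------------


#: Minimum mean silhouette required before a drifted batch is split into
#: more than one descendant. A single noisy cloud of documents typically
#: scores ~0.1 at any K, so splitting on merely positive silhouettes
#: shatters coherent topics; 0.25 is the conventional floor below which
#: cluster structure is considered weak.
MIN_SILHOUETTE = 0.25


def _choose_k(X: np.ndarray, k_max: int, seed: int,
              min_silhouette: float = MIN_SILHOUETTE) -> int:
    """Pick K by best mean silhouette over 2..min(k_max, n-1).

    Falls back to K=1 for fewer than 3 points or when no K reaches
    ``min_silhouette`` (no credible multi-cluster structure).
    """
    n = X.shape[0]
    if n < 3:
        return 1
    best_k, best_score = 1, min_silhouette
    for k in range(2, min(k_max, n - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def spawn_topics(
    drifted: Sequence[tuple[DocVector, int]],
    terms: Sequence[str],
    k_max: int,
    seed: int,
    slice_index: int,
    next_id: int,
) -> tuple[list[Topic], set[tuple[int, int]]]:
    """Cluster a slice's drifted documents into descendant topics.

    ``drifted`` pairs each document with the id of the topic that rejected
    it. K is selected by silhouette (see :func:`_choose_k`); every new
    topic receives a lineage edge from each parent whose rejected documents
    it absorbed.
    """
    if not drifted:
        raise ValueError("spawn_topics requires at least one drifted document")
    docs = [d for d, _ in drifted]
    parents = [p for _, p in drifted]
    X = np.vstack([d.vector for d in docs])
    k = _choose_k(X, k_max, seed)
    if k == 1:
        labels = np.zeros(len(docs), dtype=int)
    else:
        labels = KMeans(n_clusters=k, n_init=10,
                        random_state=seed).fit_predict(X)
    topics: list[Topic] = []
    edges: set[tuple[int, int]] = set()
    for cluster in range(k):
        idx = [i for i, lab in enumerate(labels) if lab == cluster]
        topic = _make_topic(next_id + cluster, slice_index,
                            [docs[i] for i in idx], terms)
        topics.append(topic)
        for i in idx:
            edges.add((parents[i], topic.id))
    return topics, edges


# ---------------------------------------------------------------------------
# The streaming loop
# ---------------------------------------------------------------------------


def run_sep(
    stream: DocStream,
    sigma: float = 0.1,
    k_max: int = 10,
    seed: int = 0,
) -> SEPGraph:
    """Run the full streaming topic-evolution pass over a document stream.

    Slice 0 seeds the initial topic. Slice-1 documents are tested against
    that topic only; from slice 2 on, each document's candidate is the
    cosine-nearest existing topic. Classification uses the topic state at
    the start of the slice; assigned documents are folded in and drifted
    documents clustered into descendants once, at slice end, so document
    order within a slice is irrelevant.
    """
    if stream.n_slices < 2:
        raise ValueError("SEP needs at least 2 slices")
    first_nonempty = next(
        (i for i, s in enumerate(stream.slices) if s), None)
    if first_nonempty is None:
        raise ValueError("stream contains no documents")

    topics: dict[int, Topic] = {}
    initial = init_topic(stream.slices[first_nonempty], stream.terms)
    topics[initial.id] = initial
    edges: set[tuple[int, int]] = set()

    for s in range(first_nonempty + 1, stream.n_slices):
        docs = stream.slices[s]
        if not docs:
            continue
        # snapshot of centroids at slice start, in stable id order
        ids = sorted(topics)
        centroids = np.vstack([topics[i].centroid for i in ids])
        norms = np.linalg.norm(centroids, axis=1)

        pending: dict[int, list[DocVector]] = {i: [] for i in ids}
        drifted: list[tuple[DocVector, int]] = []
        only_initial = len(ids) == 1
        for doc in docs:
            if only_initial:
                cand = ids[0]
            else:
                cos = centroids @ doc.vector / np.where(norms > 0, norms, 1.0)
                cand = ids[int(np.argmax(cos))]  # argmax takes lowest id on ties
            if drift_test(doc, topics[cand], sigma) == "assigned":
                pending[cand].append(doc)
            else:
                drifted.append((doc, cand))

        for tid in ids:
            if pending[tid]:
                update_topic(topics[tid], pending[tid], stream.terms)
        if drifted:
            new_topics, new_edges = spawn_topics(
                drifted, stream.terms, k_max=k_max, seed=seed + s,
                slice_index=s, next_id=max(topics) + 1)
            for t in new_topics:
                topics[t.id] = t
            edges |= new_edges

    assignment = {pmid: t.id for t in topics.values() for pmid in t.members}
    return SEPGraph(topics=topics, edges=edges, assignment=assignment)


# ---------------------------------------------------------------------------
# Reporting and export
# ---------------------------------------------------------------------------


def sep_statistics(graph: SEPGraph, list_top: int = 10) -> dict:
    """Summary statistics of a topic lineage graph.

    Member-count spread uses the population standard deviation. The
    per-topic listing is formatted ``label [birth slice] — count``.
    """
    if not graph.topics:
        raise ValueError("empty SEP graph")
    counts = [t.size for t in graph.topics.values()]
    ordered = sorted(graph.topics.values(),
                     key=lambda t: (-t.size, t.label, t.id))
    return {
        "n_topics": len(counts),
        "n_edges": len(graph.edges),
        "n_documents": sum(counts),
        "max_members": max(counts),
        "min_members": min(counts),
        "mean_members": float(np.mean(counts)),
        "std_members": float(np.std(counts)),  # population std dev
        "topics": [f"{t.label} [{t.birth_slice}] — {t.size}"
                   for t in ordered[:list_top]],
    }


def export_sep_graphml(graph: SEPGraph, path: str | Path) -> None:
    g = nx.DiGraph()
    for t in graph.topics.values():
        g.add_node(t.id, label=t.label, birth_slice=t.birth_slice,
                   member_count=t.size, radius=t.radius)
    g.add_edges_from(sorted(graph.edges))
    nx.write_graphml(g, path)


def write_membership_csv(graph: SEPGraph, path: str | Path) -> None:
    import csv as _csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        w = _csv.writer(handle)
        w.writerow(["pmid", "topic_id", "topic_label", "birth_slice"])
        for pmid in sorted(graph.assignment, key=str):
            t = graph.topics[graph.assignment[pmid]]
            w.writerow([pmid, t.id, t.label, t.birth_slice])


def undirected_projection(graph: SEPGraph) -> "nx.Graph":
    """Undirected view of the lineage graph (for community coloring)."""
    g = nx.Graph()
    g.add_nodes_from(graph.topics)
    g.add_edges_from((a, b) for a, b in graph.edges)
    return g


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Salton cosine between two term vectors."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    return float(math.dist(a, b)) if a.ndim == 1 else float(np.linalg.norm(a - b))
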