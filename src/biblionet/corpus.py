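"""Literature corpus ingestion and descriptive profiling.

Reads PubMed exports in MEDLINE flat-file format, normalizes free-text
fields into analysis-ready units (term n-grams, institution/country pairs,
publication dates), and produces the descriptive statistics that open any
bibliometric study: the monthly publication trend and top-N rankings of
countries, institutions and journals.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import Medline
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

logger = logging.getLogger(__name__)

__all__ = [
    "PublicationRecord",
    "Corpus",
    "TermVocabulary",
    "parse_medline",
    "write_medline",
    "extract_terms",
    "normalize_token",
    "term_frequencies",
    "AffiliationCleaner",
    "clean_affiliations",
    "monthly_trend",
    "top_n",
    "journal_frequencies",
    "write_trend_csv",
    "write_top_n_csv",
]

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}

_INSTITUTION_KEYWORDS = (
    "university", "college", "hospital", "institute", "academy",
    "center", "centre",
)


@dataclass
class PublicationRecord:
    """One literature record with the fields this pipeline consumes."""

    pmid: str
    title: str = ""
    abstract: str = ""
    journal: str = ""
    pub_year: int | None = None
    pub_month: int | None = None
    affiliations: list[str] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("PublicationRecord requires a nonempty pmid")
        if self.pub_month is not None and self.pub_year is None:
            raise ValueError("pub_month present requires pub_year")

    @property
    def text(self) -> str:
        """Title and abstract joined for term extraction."""
        return f"{self.title}. {self.abstract}" if self.abstract else self.title


@dataclass
class Corpus:
    """Ordered, pmid-unique collection of publication records."""

    records: list[PublicationRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.pmid in seen:
                raise ValueError(f"duplicate pmid in corpus: {rec.pmid}")
            seen.add(rec.pmid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PublicationRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PublicationRecord:
        return self.records[i]

    @property
    def pmids(self) -> list[str]:
        return [r.pmid for r in self.records]


@dataclass
class TermVocabulary:
    """Normalized terms surviving a document-frequency threshold."""

    terms: list[str]
    doc_frequency: dict[str, int]
    min_df: int
    ngram_max: int = 3

    def __post_init__(self) -> None:
        for t in self.terms:
            if self.doc_frequency.get(t, 0) < self.min_df:
                raise ValueError(f"term below min_df in vocabulary: {t!r}")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.doc_frequency


# ---------------------------------------------------------------------------
# MEDLINE flat-file I/O
# ---------------------------------------------------------------------------

_DP_RE = re.compile(r"^\s*(\d{4})(?:\s+([A-Za-z]+|\d{1,2}))?")


def _parse_dp(dp: str) -> tuple[int | None, int | None]:
    """Parse a MEDLINE DP field into (year, month).

    Accepts month names ("Jun", "June") and numerals ("06"); seasons or
    quarters yield month=None since they do not map to a single month.
    """
    m = _DP_RE.match(dp or "")
    if not m:
        return None, None
    year = int(m.group(1))
    tok = m.group(2)
    if tok is None:
        return year, None
    if tok.isdigit():
        month = int(tok)
        return year, month if 1 <= month <= 12 else None
    return year, _MONTHS.get(tok[:3].lower())


def parse_medline(source: str | Path | IO[str]) -> Corpus:
    """Parse a MEDLINE flat file into a :class:`Corpus`.

    Records without a PMID are skipped with a warning; for duplicate PMIDs
    the first occurrence wins. File order is preserved.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return parse_medline(handle)

    records: list[PublicationRecord] = []
    seen: set[str] = set()
    n_skipped = n_dup = 0
    for raw in Medline.parse(source):
        pmid = raw.get("PMID", "")
        if not pmid:
            n_skipped += 1
            logger.warning("skipping MEDLINE record without PMID (title=%r)",
                           raw.get("TI", "")[:60])
            continue
        if pmid in seen:
            n_dup += 1
            logger.warning("duplicate PMID %s: keeping first occurrence", pmid)
            continue
        seen.add(pmid)
        year, month = _parse_dp(raw.get("DP", ""))
        records.append(PublicationRecord(
            pmid=pmid,
            title=raw.get("TI", ""),
            abstract=raw.get("AB", ""),
            journal=raw.get("JT", ""),
            pub_year=year,
            pub_month=month if year is not None else None,
            affiliations=list(raw.get("AD", [])),
            mesh_terms=list(raw.get("MH", [])),
        ))
    if n_skipped or n_dup:
        logger.info("parse_medline: %d records kept, %d skipped (no PMID), "
                    "%d duplicates dropped", len(records), n_skipped, n_dup)
    return Corpus(records=records, provenance="medline")


def write_medline(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back to MEDLINE flat-file format.

    Covers exactly the tags :func:`parse_medline` reads (PMID/TI/AB/JT/DP/
    AD/MH), so parse∘write round-trips those fields.
    """
    def tag(handle: IO[str], name: str, value: str) -> None:
        if value:
            handle.write(f"{name:<4}- {value}\n")

    with open(path, "w", encoding="utf-8") as handle:
        for rec in corpus:
            tag(handle, "PMID", rec.pmid)
            if rec.pub_year is not None:
                dp = str(rec.pub_year)
                if rec.pub_month is not None:
                    abbr = [k for k, v in _MONTHS.items() if v == rec.pub_month][0]
                    dp += " " + abbr.capitalize()
                tag(handle, "DP", dp)
            tag(handle, "TI", rec.title)
            tag(handle, "AB", rec.abstract)
            tag(handle, "JT", rec.journal)
            for ad in rec.affiliations:
                tag(handle, "AD", ad)
            for mh in rec.mesh_terms:
                tag(handle, "MH", mh)
            handle.write("\n")


# ---------------------------------------------------------------------------
# Term extraction
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z][A-Za-z0-9'-]*")
_CHUNK_RE = re.compile(r"[.,;:!?()\[\]{}\"]+")


def normalize_token(token: str) -> str:
    """Lowercase a token and fold common English plural suffixes.

    Suffix rules only ("genes"→"gene", "viruses"→"virus",
    "pathologies"→"pathology"); words ending in -ss/-us/-is are left alone.
    Idempotent: normalizing an already-normalized token is a no-op.
    """
    w = token.lower()
    if len(w) <= 3 or w.endswith(("ss", "us", "is")):
        return w
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-3] + "y"
    if w.endswith(("ches", "shes", "xes", "zes")):
        return w[:-2]
    if w.endswith("s"):
        return w[:-1]
    return w


def _token_runs(text: str) -> Iterator[list[str]]:
    """Yield runs of normalized, stopword-free tokens between punctuation.

    N-grams never span a punctuation boundary.
    """
    for chunk in _CHUNK_RE.split(text):
        run = []
        for tok in _TOKEN_RE.findall(chunk):
            if tok.lower() in ENGLISH_STOP_WORDS:
                if run:
                    yield run
                    run = []
                continue
            norm = normalize_token(tok)
            if norm in ENGLISH_STOP_WORDS or len(norm) < 2:
                if run:
                    yield run
                    run = []
                continue
            run.append(norm)
        if run:
            yield run


def _doc_ngrams(text: str, ngram_max: int) -> Iterator[str]:
    for run in _token_runs(text):
        for n in range(1, ngram_max + 1):
            for i in range(len(run) - n + 1):
                yield " ".join(run[i:i + n])


def extract_terms(
    corpus: Corpus, min_df: int = 5, ngram_max: int = 3,
) -> tuple[TermVocabulary, list[set[str]]]:
    """Extract a document-frequency-thresholded term vocabulary.

    Terms are lowercased word n-grams (1..``ngram_max``) over title +
    abstract, after stopword removal and plural folding. Terms appearing in
    fewer than ``min_df`` documents are dropped. Returns the vocabulary and,
    per record (in corpus order), the set of surviving terms it contains.
    """
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if ngram_max not in (1, 2, 3):
        raise ValueError("ngram_max must be 1, 2 or 3")
    doc_sets = [set(_doc_ngrams(rec.text, ngram_max)) for rec in corpus]
    df = Counter(t for s in doc_sets for t in s)
    kept = {t: c for t, c in df.items() if c >= min_df}
    vocab = TermVocabulary(
        terms=sorted(kept), doc_frequency=kept, min_df=min_df,
        ngram_max=ngram_max,
    )
    return vocab, [s & kept.keys() for s in doc_sets]


def term_frequencies(record: PublicationRecord,
                     vocabulary: TermVocabulary) -> Counter:
    """Occurrence counts of vocabulary terms in one record's text.

    Counts every n-gram occurrence (not document presence); used to build
    term-frequency document vectors.
    """
    counts: Counter = Counter()
    for gram in _doc_ngrams(record.text, vocabulary.ngram_max):
        if gram in vocabulary:
            counts[gram] += 1
    return counts


# ---------------------------------------------------------------------------
# Affiliation cleaning
# ---------------------------------------------------------------------------


@dataclass
class AffiliationCleaner:
    """Resolve raw affiliation strings to (institution, country) pairs.

    ``alias_table`` maps known raw institution variants to canonical names;
    ``country_gazetteer`` maps country-name variants (e.g. "UK") to
    canonical country names. Strings resolving to neither are recorded in
    :attr:`unresolved`.
    """

    alias_table: Mapping[str, str] = field(default_factory=dict)
    country_gazetteer: Mapping[str, str] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.country_gazetteer, Mapping):
            self.country_gazetteer = {c: c for c in self.country_gazetteer}
        self._alias_lc = {k.strip().lower(): v
                          for k, v in self.alias_table.items()}
        self._gaz_lc = {k.strip().lower(): v
                        for k, v in self.country_gazetteer.items()}

    def clean_one(self, raw: str) -> tuple[str | None, str | None]:
        segments = [s.strip().rstrip(".") for s in raw.split(",")]
        segments = [s for s in segments if s]
        institution = None
        for seg in segments:
            hit = self._alias_lc.get(seg.lower())
            if hit:
                institution = hit
                break
        if institution is None:
            for seg in segments:
                if any(kw in seg.lower() for kw in _INSTITUTION_KEYWORDS):
                    institution = seg
                    break
        country = None
        for seg in segments:  # last gazetteer match wins
            hit = self._gaz_lc.get(seg.lower())
            if hit:
                country = hit
        if institution is None and country is None:
            self.unresolved.append(raw)
        return institution, country

    def clean_record(
        self, record: PublicationRecord,
    ) -> list[tuple[str | None, str | None]]:
        return [self.clean_one(a) for a in record.affiliations]

    def write_log(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(line + "\n" for line in self.unresolved), encoding="utf-8")


def clean_affiliations(
    record: PublicationRecord,
    alias_table: Mapping[str, str],
    country_gazetteer: Mapping[str, str] | Sequence[str],
) -> list[tuple[str | None, str | None]]:
    """Functional wrapper over :class:`AffiliationCleaner` for one record."""
    gaz = (country_gazetteer if isinstance(country_gazetteer, Mapping)
           else {c: c for c in country_gazetteer})
    return AffiliationCleaner(alias_table, gaz).clean_record(record)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------


def monthly_trend(
    corpus: Corpus, cutoff: tuple[int, int],
) -> tuple[list[tuple[int, int, int]], int]:
    """Monthly publication counts up to a (year, month) cutoff.

    Records missing the month, or dated after the cutoff, are excluded and
    reported separately (second return value). The series covers the
    contiguous month range observed, zero-filled, so that
    sum(counts) + excluded == len(corpus).
    """
    cy, cm = cutoff
    if not (1 <= cm <= 12):
        raise ValueError("cutoff month must be in 1..12")
    counts: Counter = Counter()
    excluded = 0
    for rec in corpus:
        if rec.pub_year is None or rec.pub_month is None:
            excluded += 1
        elif (rec.pub_year, rec.pub_month) > (cy, cm):
            excluded += 1
        else:
            counts[(rec.pub_year, rec.pub_month)] += 1
    if not counts:
        return [], excluded
    lo, hi = min(counts), max(counts)
    series = []
    y, m = lo
    while (y, m) <= hi:
        series.append((y, m, counts.get((y, m), 0)))
        m += 1
        if m > 12:
            y, m = y + 1, 1
    return series, excluded


def top_n(entities: Mapping[str, int], n: int) -> list[tuple[str, int]]:
    """Top-``n`` entities by count, ties broken lexicographically by name."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(entities.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def journal_frequencies(corpus: Corpus) -> Counter:
    return Counter(r.journal for r in corpus if r.journal)


def write_trend_csv(series: Iterable[tuple[int, int, int]], excluded: int,
                    path: str | Path) -> None:
    """Trend table: columns year, month, publications; excluded row last."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        w = csv.writer(handle)
        w.writerow(["year", "month", "publications"])
        for y, m, c in series:
            w.writerow([y, m, c])
        w.writerow(["excluded", "", excluded])


def write_top_n_csv(ranked: Iterable[tuple[str, int]], label: str,
                    path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        w = csv.writer(handle)
        w.writerow(["rank", label, "publications"])
        for i, (name, count) in enumerate(ranked, 1):
            w.writerow([i, name, count])
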