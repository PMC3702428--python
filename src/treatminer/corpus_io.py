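"""Corpus input/output: citation XML, clinical-trial XML, sentence TSV.

Documents are split into sentences with a deterministic rule-based splitter;
the title of a citation is sentence 0 and abstract sentences follow, because
article titles ("DRUG for the treatment of DISEASE: a case report") are a
rich source of treatment statements.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable, Sequence, Union

from lxml import etree

logger = logging.getLogger(__name__)

XmlSource = Union[str, bytes, BinaryIO]


@dataclass(frozen=True)
class DocumentRecord:
    """One citation: a PMID-like identifier, a title and an (optional) abstract."""

    doc_id: str
    title: str
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not (self.title.strip() or self.abstract.strip()):
            raise ValueError(f"document {self.doc_id!r}: title and abstract both empty")


@dataclass(frozen=True)
class SentenceRecord:
    """One sentence of a document; sentence_index is 0-based and contiguous."""

    doc_id: str
    sentence_index: int
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("sentence text must be non-empty")
        if self.sentence_index < 0:
            raise ValueError("sentence_index must be >= 0")


@dataclass(frozen=True)
class TrialRecord:
    """A clinical-trial registry study: free-text conditions and interventions."""

    trial_id: str
    condition_texts: tuple[str, ...] = ()
    intervention_texts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValueError("trial_id must be non-empty")


class SchemaError(ValueError):
    """A tabular input is missing a required column."""


# --------------------------------------------------------------------------
# Sentence splitting
# --------------------------------------------------------------------------

#: Abbreviations whose trailing period never ends a sentence.
_ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "vs", "etc", "dr", "mr", "mrs", "ms", "prof", "fig",
        "figs", "al", "st", "no", "ca", "approx", "resp", "cf",
    }
)

_BOUNDARY_RE = re.compile(r"([.?!]+)(\s+)(?=[A-Z0-9])")


def split_sentences(text: str) -> list[str]:
    """Split plain text into sentences.

    Rule-based and deterministic: a boundary is one or more of ``. ? !``
    followed by whitespace and an uppercase letter or digit, unless the
    period terminates a known abbreviation or the candidate boundary sits
    inside an unbalanced parenthetical span.  The concatenation of the
    returned sentences (modulo inter-sentence whitespace) equals the trimmed
    input, so no content is lost.
    """
    text = text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end(1)  # include terminal punctuation
        candidate = text[start:end]
        # no split inside an open parenthesis / bracket
        if candidate.count("(") != candidate.count(")"):
            continue
        if candidate.count("[") != candidate.count("]"):
            continue
        last_word = re.search(r"([A-Za-z][A-Za-z.]*)\.$", candidate)
        if last_word and last_word.group(1).lower().rstrip(".") in _ABBREVIATIONS:
            continue
        # single capital initial ("J. Smith") is not a boundary
        if last_word and len(last_word.group(1)) == 1 and last_word.group(1).isupper():
            continue
        if candidate.strip():
            sentences.append(candidate.strip())
            start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


_SECTION_LABEL_RE = re.compile(r"^[A-Z][A-Z /&-]{2,}:\s*")


def documents_to_sentences(
    documents: Iterable[DocumentRecord],
    strip_section_labels: bool = False,
) -> list[SentenceRecord]:
    """Segment documents into SentenceRecords.

    The title becomes sentence_index 0 (titles are kept whole — they rarely
    contain internal boundaries and often carry the treatment pattern);
    abstract sentences follow.  Structured-abstract section labels such as
    ``CONCLUSIONS:`` are kept by default and stripped only on request.
    """
    out: list[SentenceRecord] = []
    for doc in documents:
        idx = 0
        title = doc.title.strip()
        if title:
            out.append(SentenceRecord(doc.doc_id, idx, title))
            idx += 1
        for sent in split_sentences(doc.abstract):
            if strip_section_labels:
                sent = _SECTION_LABEL_RE.sub("", sent)
                if not sent:
                    continue
            out.append(SentenceRecord(doc.doc_id, idx, sent))
            idx += 1
    return out


# --------------------------------------------------------------------------
# MEDLINE-style citation XML
# --------------------------------------------------------------------------

def _element_text(el: etree._Element | None) -> str:
    if el is None:
        return ""
    return " ".join("".join(el.itertext()).split())


def parse_medline_xml(source: XmlSource) -> list[DocumentRecord]:
    """Parse MEDLINE/PubMed baseline citation XML into DocumentRecords.

    One record per ``MedlineCitation`` (or ``PubmedArticle``) element, in
    document order.  A missing abstract maps to the empty string; the parts
    of a structured abstract are concatenated in document order with single
    spaces.  Citations lacking a PMID are skipped with a warning.

    Raises ``lxml.etree.XMLSyntaxError`` (which reports the byte offset) on
    malformed input.
    """
    if isinstance(source, str):
        source = source.encode("utf-8")
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(source).getroot()

    if root.tag == "MedlineCitation":
        citations: list[etree._Element] = [root]
    else:
        citations = list(root.iter("MedlineCitation"))

    records: list[DocumentRecord] = []
    for cit in citations:
        pmid = _element_text(cit.find("PMID"))
        if not pmid:
            logger.warning("citation without PMID skipped")
            continue
        article = cit.find("Article")
        title = _element_text(article.find("ArticleTitle")) if article is not None else ""
        abstract_parts: list[str] = []
        abstract_el = article.find("Abstract") if article is not None else None
        if abstract_el is not None:
            for part in abstract_el.findall("AbstractText"):
                txt = _element_text(part)
                label = (part.get("Label") or "").strip()
                if txt and label:
                    txt = f"{label}: {txt}"
                if txt:
                    abstract_parts.append(txt)
        records.append(DocumentRecord(pmid, title, " ".join(abstract_parts)))
    return records


# --------------------------------------------------------------------------
# ClinicalTrials.gov study XML
# --------------------------------------------------------------------------

def parse_clinicaltrials_xml(source: XmlSource) -> TrialRecord:
    """Parse one ClinicalTrials.gov study record.

    Captures every ``condition`` and ``intervention/intervention_name`` text
    verbatim; interventions of non-drug type are kept too — deciding which
    interventions name drugs is the seed builder's job, done against the
    drug lexicon.
    """
    if isinstance(source, str):
        source = source.encode("utf-8")
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(source).getroot()

    trial_id = _element_text(root.find("id_info/nct_id")) or _element_text(root.find("nct_id"))
    if not trial_id:
        raise ValueError("study record lacks an nct_id")
    conditions = tuple(t for el in root.findall("condition") if (t := _element_text(el)))
    interventions = tuple(
        t for el in root.findall("intervention/intervention_name") if (t := _element_text(el))
    )
    return TrialRecord(trial_id, conditions, interventions)


# --------------------------------------------------------------------------
# TSV plumbing (no quoting; tabs/newlines inside fields become spaces)
# --------------------------------------------------------------------------

def _clean_field(value: str) -> str:
    return re.sub(r"[\t\r\n]+", " ", value)


def write_sentences_tsv(sentences: Iterable[SentenceRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("doc_id\tsentence_index\ttext\n")
        for s in sentences:
            fh.write(f"{_clean_field(s.doc_id)}\t{s.sentence_index}\t{_clean_field(s.text)}\n")


def load_sentences_tsv(path) -> list[SentenceRecord]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in ("doc_id", "sentence_index", "text"):
            if col not in header:
                raise SchemaError(f"sentence TSV {path!s} missing column {col!r}")
        idx = {c: i for i, c in enumerate(header)}
        out = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            out.append(
                SentenceRecord(
                    fields[idx["doc_id"]],
                    int(fields[idx["sentence_index"]]),
                    fields[idx["text"]],
                )
            )
    return out


def write_pairs_tsv(pairs, path, extra_columns: Sequence[str] = ()) -> None:
    """Write (drug, disease) pairs sorted lexicographically (drug, disease).

    ``pairs`` may be an iterable of DrugDiseasePair or of tuples whose first
    two elements are drug and disease; values for ``extra_columns`` follow.
    """
    rows = []
    for p in pairs:
        if hasattr(p, "drug"):
            rows.append((p.drug, p.disease))
        else:
            rows.append(tuple(p))
    rows.sort(key=lambda r: (r[0], r[1]))
    header = "drug\tdisease" + ("".join("\t" + c for c in extra_columns)) + "\n"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header)
        for row in rows:
            fh.write("\t".join(_clean_field(str(v)) for v in row) + "\n")


def load_pairs_tsv(path) -> list[tuple[str, str]]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in ("drug", "disease"):
            if col not in header:
                raise SchemaError(f"pair TSV {path!s} missing column {col!r}")
        idx = {c: i for i, c in enumerate(header)}
        out = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            out.append((fields[idx["drug"]], fields[idx["disease"]]))
    return out
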