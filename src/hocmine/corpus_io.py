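"""Corpus readers and writers.

Two representations flow through the pipeline:

* **MEDLINE/PubMed XML** abstracts (``PubmedArticle`` elements), carrying the
  MeSH descriptors and chemical-substance metadata that later become MESH and
  CHEM features.  Metadata is attached at abstract level by PubMed, so after
  sentence segmentation it is inherited by every sentence of the abstract.

* **Annotated-corpus TSV**: one sentence per line with columns
  ``pmid\\tsent_index\\tlabels\\ttext`` where ``labels`` is a pipe-separated
  list of taxonomy codes (or unambiguous node names), empty for unlabeled
  sentences.  Roughly three quarters of sentences in a hallmark-annotated
  corpus carry no label at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set

from lxml import etree

from ._text import (
    LowercaseLemmatizer,
    RegexSentenceSegmenter,
    RegexTokenizer,
)
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "SentenceRecord",
    "AbstractRecord",
    "read_medline_xml",
    "write_medline_xml",
    "split_sentences",
    "read_annotated_corpus",
    "write_annotated_corpus",
    "label_distribution",
    "CorpusFormatError",
]


class CorpusFormatError(ValueError):
    """Malformed corpus input (bad XML, unknown label token, ...)."""


@dataclass
class SentenceRecord:
    """One sentence with its gold and/or predicted hallmark labels.

    ``mesh_terms`` and ``chemicals`` are inherited verbatim from the parent
    abstract.  ``gold_labels`` holds codes exactly as annotated; hypernym
    closure is applied explicitly at training time, not here.
    """

    pmid: str
    index: int
    text: str
    tokens: List[str] = field(default_factory=list)
    lemmas: List[str] = field(default_factory=list)
    gold_labels: Set[str] = field(default_factory=set)
    predicted_labels: Set[str] = field(default_factory=set)
    mesh_terms: List[str] = field(default_factory=list)
    chemicals: List[str] = field(default_factory=list)

    @property
    def sentence_id(self):
        return (self.pmid, self.index)


@dataclass
class AbstractRecord:
    pmid: str
    title: str
    body: str
    mesh_terms: List[str] = field(default_factory=list)
    chemicals: List[str] = field(default_factory=list)
    sentences: List[SentenceRecord] = field(default_factory=list)


# --------------------------------------------------------------- MEDLINE XML


def read_medline_xml(path) -> List[AbstractRecord]:
    """Parse PubmedArticle records from a MEDLINE/PubMed XML file.

    Articles without abstract text are skipped with a warning.  Missing
    MeshHeadingList/ChemicalList yield empty metadata lists.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"malformed MEDLINE XML in {path}: {exc}") from exc
    records: List[AbstractRecord] = []
    seen: Set[str] = set()
    for article in tree.iter("PubmedArticle"):
        pmid = article.findtext(".//MedlineCitation/PMID") or article.findtext(".//PMID")
        pmid = (pmid or "").strip()
        title = (article.findtext(".//ArticleTitle") or "").strip()
        abstract_parts = [
            "".join(el.itertext()).strip()
            for el in article.findall(".//Abstract/AbstractText")
        ]
        body = " ".join(p for p in abstract_parts if p).strip()
        if not body:
            logger.warning("skipping article %s: no abstract text", pmid or "<no pmid>")
            continue
        if pmid in seen:
            raise CorpusFormatError(f"duplicate PMID {pmid!r} in {path}")
        seen.add(pmid)
        mesh = [
            el.text.strip()
            for el in article.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
            if el.text and el.text.strip()
        ]
        chem = [
            el.text.strip()
            for el in article.findall(".//ChemicalList/Chemical/NameOfSubstance")
            if el.text and el.text.strip()
        ]
        records.append(
            AbstractRecord(pmid=pmid, title=title, body=body, mesh_terms=mesh, chemicals=chem)
        )
    return records


def write_medline_xml(records: Sequence[AbstractRecord], path) -> None:
    """Write abstracts as minimal PubmedArticle XML (round-trips through
    :func:`read_medline_xml`)."""
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        article = etree.SubElement(root, "PubmedArticle")
        citation = etree.SubElement(article, "MedlineCitation")
        etree.SubElement(citation, "PMID").text = rec.pmid
        art = etree.SubElement(citation, "Article")
        etree.SubElement(art, "ArticleTitle").text = rec.title
        abstract = etree.SubElement(art, "Abstract")
        etree.SubElement(abstract, "AbstractText").text = rec.body
        if rec.mesh_terms:
            mesh_list = etree.SubElement(citation, "MeshHeadingList")
            for term in rec.mesh_terms:
                heading = etree.SubElement(mesh_list, "MeshHeading")
                etree.SubElement(heading, "DescriptorName").text = term
        if rec.chemicals:
            chem_list = etree.SubElement(citation, "ChemicalList")
            for name in rec.chemicals:
                chem = etree.SubElement(chem_list, "Chemical")
                etree.SubElement(chem, "NameOfSubstance").text = name
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


# ------------------------------------------------------------- segmentation


def split_sentences(
    record: AbstractRecord,
    segmenter=None,
    tokenizer=None,
    lemmatizer=None,
) -> AbstractRecord:
    """Populate ``record.sentences`` in place (and return the record).

    Indices run consecutively from 0; every sentence inherits the abstract's
    PMID, MeSH terms and chemicals.  An empty body leaves the record
    unchanged with a warning.
    """
    segmenter = segmenter or RegexSentenceSegmenter()
    tokenizer = tokenizer or RegexTokenizer()
    lemmatizer = lemmatizer or LowercaseLemmatizer()
    if not record.body.strip():
        logger.warning("abstract %s has empty body; nothing to segment", record.pmid)
        return record
    sentences = []
    for i, text in enumerate(segmenter.segment(record.body)):
        tokens = tokenizer.tokenize(text)
        sentences.append(
            SentenceRecord(
                pmid=record.pmid,
                index=i,
                text=text,
                tokens=tokens,
                lemmas=lemmatizer.lemmatize(tokens),
                mesh_terms=list(record.mesh_terms),
                chemicals=list(record.chemicals),
            )
        )
    record.sentences = sentences
    return record


# -------------------------------------------------------- annotated corpus


def read_annotated_corpus(
    path,
    taxonomy: Taxonomy,
    converter: Optional[Callable[[str], List[str]]] = None,
    tokenizer=None,
    lemmatizer=None,
) -> List[SentenceRecord]:
    """Read the sentence-level annotated corpus TSV.

    Label tokens may be taxonomy codes or unambiguous node names; anything
    else raises :class:`CorpusFormatError` naming the offending line.  A
    ``converter`` hook may map a raw line to the canonical four columns for
    alternative layouts.
    """
    tokenizer = tokenizer or RegexTokenizer()
    lemmatizer = lemmatizer or LowercaseLemmatizer()
    names = taxonomy.name_to_code()
    sentences: List[SentenceRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            columns = converter(line) if converter else line.split("\t")
            if len(columns) != 4:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(columns)}"
                )
            pmid, idx, labels_field, text = columns
            labels: Set[str] = set()
            if labels_field:
                for token in labels_field.split("|"):
                    token = token.strip()
                    if token in taxonomy:
                        labels.add(token)
                    elif token in names:
                        labels.add(names[token])
                    else:
                        raise CorpusFormatError(
                            f"{path}:{lineno}: unknown label token {token!r}"
                        )
            tokens = tokenizer.tokenize(text)
            sentences.append(
                SentenceRecord(
                    pmid=pmid,
                    index=int(idx),
                    text=text,
                    tokens=tokens,
                    lemmas=lemmatizer.lemmatize(tokens),
                    gold_labels=labels,
                )
            )
    return sentences


def _sort_key(code: str):
    return [int(p) if p.isdigit() else p for p in code.split(".")]


def write_annotated_corpus(sentences: Iterable[SentenceRecord], path) -> None:
    """Write sentences in the canonical TSV form (codes sorted numerically,
    LF endings); reading the result back and re-writing it is byte-stable."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sentences:
            labels = "|".join(sorted(s.gold_labels, key=_sort_key))
            fh.write(f"{s.pmid}\t{s.index}\t{labels}\t{s.text}\n")


def label_distribution(sentences: Sequence[SentenceRecord]) -> Dict[int, float]:
    """Proportion of sentences by number of gold labels; values sum to 1."""
    if not sentences:
        raise ValueError("empty corpus: label distribution undefined")
    counts: Dict[int, int] = {}
    for s in sentences:
        k = len(s.gold_labels)
        counts[k] = counts.get(k, 0) + 1
    total = len(sentences)
    return {k: v / total for k, v in sorted(counts.items())}
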