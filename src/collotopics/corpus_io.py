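"""Read and write article corpora, select target articles, map countries to regions.

The corpus exchange format is JSONL (one article object per line, UTF-8) with
keys ``doc_id, date, title, source, country, text``; TSV with the same column
names is accepted as an alternative. Country labels come from a closed
19-country set partitioned into five world regions (North America, Europe,
Oceania, Asia, Africa).
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "REGIONS",
    "COUNTRIES",
    "COUNTRY_ALIASES",
    "region_of",
    "canonical_country",
    "read_corpus",
    "write_corpus",
    "select_target_articles",
    "DEFAULT_TARGETS",
]

#: Five world regions partitioning the 19 recognized publication countries.
REGIONS: dict[str, frozenset[str]] = {
    "NorthAmerica": frozenset({"United States", "Canada"}),
    "Europe": frozenset({"Ireland", "United Kingdom"}),
    "Oceania": frozenset({"Australia", "New Zealand"}),
    "Asia": frozenset(
        {
            "Bangladesh",
            "Hong Kong",
            "India",
            "Malaysia",
            "Pakistan",
            "Philippines",
            "Singapore",
            "Sri Lanka",
        }
    ),
    "Africa": frozenset({"Ghana", "Kenya", "Nigeria", "South Africa", "Tanzania"}),
}

#: The closed 19-country set (union of the region member sets).
COUNTRIES: frozenset[str] = frozenset().union(*REGIONS.values())

#: Documented alias table: common metadata dialects -> canonical label.
COUNTRY_ALIASES: dict[str, str] = {
    "usa": "United States",
    "us": "United States",
    "u.s.": "United States",
    "u.s.a.": "United States",
    "united states of america": "United States",
    "uk": "United Kingdom",
    "u.k.": "United Kingdom",
    "great britain": "United Kingdom",
    "hongkong": "Hong Kong",
    "hk": "Hong Kong",
    "nz": "New Zealand",
    "sri-lanka": "Sri Lanka",
    "south-africa": "South Africa",
}

_COUNTRY_BY_LOWER = {c.lower(): c for c in COUNTRIES}

_REGION_BY_COUNTRY = {c: r for r, members in REGIONS.items() for c in members}

#: Default target keywords: surface terms selecting pregnancy articles.
DEFAULT_TARGETS: frozenset[str] = frozenset({"pregnant", "pregnancy"})

_FIELDS = ("doc_id", "date", "title", "source", "country", "text")

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:[-'’][a-z0-9]+)*")


@dataclass(frozen=True)
class Document:
    """One news article with its metadata.

    ``country`` must be one of the 19 recognized labels (after alias
    canonicalization); construction through :func:`read_corpus` enforces this.
    """

    doc_id: str
    date: str
    title: str
    source: str
    country: str
    text: str

    def to_record(self) -> dict[str, str]:
        return asdict(self)


def canonical_country(label: str) -> str:
    """Canonicalize a country label (case-insensitive, alias-aware).

    Raises ``ValueError`` listing the valid labels if the country is not in
    the closed 19-country set.
    """
    key = label.strip().lower()
    if key in _COUNTRY_BY_LOWER:
        return _COUNTRY_BY_LOWER[key]
    if key in COUNTRY_ALIASES:
        return COUNTRY_ALIASES[key]
    valid = ", ".join(sorted(COUNTRIES))
    raise ValueError(
        f"unknown country {label!r}; valid labels (case-insensitive, plus "
        f"documented aliases such as 'USA', 'UK'): {valid}"
    )


def region_of(country: str) -> str:
    """Return the region name for a country label.

    The five regions partition the 19 countries, so this is a total function
    on the closed set; anything else raises ``ValueError``.
    """
    return _REGION_BY_COUNTRY[canonical_country(country)]


def _document_from_record(record: dict, lineno: int) -> Document:
    missing = [f for f in _FIELDS if f not in record or record[f] is None]
    if missing:
        raise ValueError(
            f"malformed record at line {lineno}: missing field(s) {', '.join(missing)}"
        )
    try:
        country = canonical_country(str(record["country"]))
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc
    return Document(
        doc_id=str(record["doc_id"]),
        date=str(record["date"]),
        title=str(record["title"]),
        source=str(record["source"]),
        country=country,
        text=str(record["text"]),
    )


def read_corpus(path: str | Path, format: str | None = None) -> list[Document]:
    """Read a corpus file into an ordered list of :class:`Document`.

    Parameters
    ----------
    path
        JSONL (one article object per line) or TSV (header row) file.
    format
        ``"jsonl"`` or ``"tsv"``; inferred from the file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "jsonl"
    if format not in {"jsonl", "tsv"}:
        raise ValueError(f"unsupported corpus format {format!r} (use 'jsonl' or 'tsv')")

    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        if format == "jsonl":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"malformed JSON at line {lineno}: {exc}") from exc
                docs.append(_document_from_record(record, lineno))
        else:
            reader = csv.DictReader(fh, delimiter="\t")
            for lineno, record in enumerate(reader, start=2):
                docs.append(_document_from_record(record, lineno))

    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValueError(f"duplicate doc_id {d.doc_id!r} in corpus {path}")
        seen.add(d.doc_id)
    logger.info("read %d documents from %s", len(docs), path)
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path, format: str = "jsonl") -> None:
    """Write documents in the canonical JSONL dialect (or TSV)."""
    path = Path(path)
    docs = list(docs)
    with open(path, "w", encoding="utf-8") as fh:
        if format == "jsonl":
            for d in docs:
                fh.write(json.dumps(d.to_record(), ensure_ascii=False, sort_keys=False))
                fh.write("\n")
        elif format == "tsv":
            writer = csv.DictWriter(fh, fieldnames=list(_FIELDS), delimiter="\t")
            writer.writeheader()
            for d in docs:
                writer.writerow(d.to_record())
        else:
            raise ValueError(f"unsupported corpus format {format!r}")
    logger.info("wrote %d documents to %s", len(docs), path)


def select_target_articles(
    docs: Sequence[Document], targets: Iterable[str] = DEFAULT_TARGETS
) -> list[Document]:
    """Retain documents containing at least one target term as a surface token.

    Matching is on lowercased surface tokens (selection precedes
    lemmatization), case-insensitively and by exact token equality — so
    "Pregnant" matches but semantically adjacent words ("maternity") and
    inflected variants do not count as the target itself.
    """
    target_set = {t.lower() for t in targets}
    if not target_set:
        raise ValueError("targets must be non-empty")
    kept = [
        d for d in docs if target_set & set(_TOKEN_RE.findall(d.text.lower()))
    ]
    logger.info("selected %d of %d documents containing %s", len(kept), len(docs), sorted(target_set))
    return kept
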