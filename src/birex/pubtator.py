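"""Reader/writer for the PubTator pipe/tab corpus dialect.

Documents are blank-line separated blocks::

    <id>|t|<title>
    <id>|a|<abstract>
    <id><TAB><start><TAB><end><TAB><surface><TAB><type><TAB><identifiers>
    <id><TAB><relation type><TAB><id1><TAB><id2><TAB><novelty>

Annotation lines are recognised by their integer offset fields; everything
else with five tab-separated fields is a relation line.  Composite identifier
strings are split on ``,`` and ``;`` into a code set; ``-`` denotes an
unlinked mention.  Parsing is strict: every non-blank line must be consumed
as title, abstract, annotation or relation, otherwise a :class:`ParseError`
naming the line number is raised.
"""

from __future__ import annotations

import io
import re
from typing import IO, Iterable, Sequence

from .documents import (
    Document,
    EntityMention,
    OffsetIntegrityError,
    RelationInstance,
    mention_slice_check,
)

_UNLINKED = "-"


class ParseError(ValueError):
    pass


def _split_codes(identifiers: str) -> frozenset[str]:
    if identifiers.strip() in ("", _UNLINKED):
        return frozenset()
    return frozenset(c.strip() for c in re.split(r"[,;]", identifiers) if c.strip())


def read_pubtator(stream: IO[str] | str) -> list[Document]:
    """Parse a PubTator stream (or literal string) into Documents."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    docs: list[Document] = []
    doc: Document | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if doc is not None:
                _finish(doc, lineno)
                docs.append(doc)
                doc = None
            continue
        if "|" in line and "\t" not in line:
            doc_id, sep, rest = line.partition("|")
            kind, sep2, payload = rest.partition("|")
            if kind == "t":
                if doc is not None:
                    _finish(doc, lineno)
                    docs.append(doc)
                doc = Document(doc_id=doc_id, title=payload, abstract="")
                continue
            if kind == "a":
                if doc is None or doc.doc_id != doc_id:
                    raise ParseError(f"line {lineno}: abstract line without matching title")
                doc.abstract = payload
                continue
            raise ParseError(f"line {lineno}: unrecognised pipe line kind {kind!r}")
        fields = line.split("\t")
        if doc is None:
            raise ParseError(f"line {lineno}: annotation before any title line")
        if fields[0] != doc.doc_id:
            raise ParseError(
                f"line {lineno}: document id {fields[0]!r} does not match block {doc.doc_id!r}"
            )
        if len(fields) == 6 and _is_int(fields[1]) and _is_int(fields[2]):
            _, start_s, end_s, surface, etype, identifiers = fields
            start, end = int(start_s), int(end_s)
            if not (0 <= start < end <= len(doc.text)):
                raise ParseError(
                    f"line {lineno}: offsets [{start}, {end}) out of bounds for "
                    f"text of length {len(doc.text)}"
                )
            try:
                mention = EntityMention(start, end, surface, etype, _split_codes(identifiers))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            doc.mentions.append(mention)
        elif len(fields) == 5:
            _, rtype, id1, id2, novelty = fields
            try:
                rel = RelationInstance((id1, id2), rtype, novelty == "Novel")
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            doc.relations.append(rel)
        else:
            raise ParseError(
                f"line {lineno}: expected 6-field annotation or 5-field relation, "
                f"got {len(fields)} fields"
            )
    if doc is not None:
        _finish(doc, lineno if docs or doc.mentions else 0)
        docs.append(doc)
    return docs


def _finish(doc: Document, lineno: int) -> None:
    violations = mention_slice_check(doc)
    if violations:
        raise OffsetIntegrityError(
        f"block ending near line {lineno}: " + "; ".join(violations)
        )


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_pubtator(docs: Iterable[Document], stream: IO[str]) -> None:
    """Serialize documents in the exact dialect :func:`read_pubtator` accepts.

    Refuses to serialize documents whose mentions violate offset integrity.
    Novelty is written as ``Novel``/``No``; empty code sets as ``-``.
    """
    for doc in docs:
        violations = mention_slice_check(doc)
        if violations:
            raise OffsetIntegrityError("; ".join(violations))
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for m in doc.mentions:
            codes = ",".join(sorted(m.codes)) if m.codes else _UNLINKED
            stream.write(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.entity_type}\t{codes}\n"
            )
        for r in doc.relations:
            novelty = "Novel" if r.novelty else "No"
            stream.write(
                f"{doc.doc_id}\t{r.relation_type}\t{r.pair[0]}\t{r.pair[1]}\t{novelty}\n"
            )
        stream.write("\n")


def dumps(docs: Sequence[Document]) -> str:
    buf = io.StringIO()
    write_pubtator(docs, buf)
    return buf.getvalue()
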