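"""End-to-end orchestration: Tagger -> Linker -> Extractor with a run report.

Each stage boundary is a valid in-memory (and, through the CLI, on-disk
PubTator) document set, so stages can run separately or end-to-end with
bit-identical results.  The run report counts what each stage did: mentions
tagged, a histogram of linker resolution stages, and candidate pairs
generated versus relations kept.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .documents import Document
from .encoding import TokenEncoder
from .extractor.model import ExtractorModel, predict_relations
from .extractor.pairs import DEFAULT_TYPE_PAIRS, generate_pairs, group_entities
from .linker.cascade import LinkerConfig, TrainDictionary, link_document
from .linker.kb import Embedder, EmbeddingIndex, KnowledgeBase
from .linker.variants import VariantLookup
from .tagger.model import TaggerModel, tag_document

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, doc_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on document {doc_id!r}: {cause}")
        self.stage, self.doc_id = stage, doc_id


@dataclass
class PipelineConfig:
    tagger: TaggerModel | None = None
    extractor: ExtractorModel | None = None
    kbs: Mapping[str, KnowledgeBase] = field(default_factory=dict)
    indexes: Mapping[str, EmbeddingIndex] = field(default_factory=dict)
    train_dict: TrainDictionary = field(default_factory=dict)
    linker: LinkerConfig = field(default_factory=LinkerConfig)
    embedder: Embedder | None = None
    variant_lookup: VariantLookup | None = None


@dataclass
class RunReport:
    n_docs: int = 0
    mentions_tagged: int = 0
    stage_histogram: dict[str, int] = field(default_factory=dict)
    pairs_generated: int = 0
    relations_kept: int = 0
    seconds_per_doc: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_docs": self.n_docs,
            "mentions_tagged": self.mentions_tagged,
            "stage_histogram": dict(sorted(self.stage_histogram.items())),
            "pairs_generated": self.pairs_generated,
            "relations_kept": self.relations_kept,
        }


def tag_stage(docs: Sequence[Document], config: PipelineConfig) -> list[Document]:
    out = []
    for doc in docs:
        try:
            mentions = tag_document(doc, config.tagger)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("tagger", doc.doc_id, exc) from exc
        out.append(Document(doc.doc_id, doc.title, doc.abstract, mentions=mentions))
    return out


def link_stage(
    docs: Sequence[Document], config: PipelineConfig, report: RunReport | None = None
) -> list[Document]:
    out = []
    for doc in docs:
        try:
            linked, decisions = link_document(
                doc,
                config.kbs,
                config.indexes,
                config.train_dict,
                config.linker,
                config.embedder,
                config.variant_lookup,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("linker", doc.doc_id, exc) from exc
        if report is not None:
            for d in decisions:
                report.stage_histogram[d.stage] = report.stage_histogram.get(d.stage, 0) + 1
        out.append(linked)
    return out


def extract_stage(
    docs: Sequence[Document], config: PipelineConfig, report: RunReport | None = None
) -> list[Document]:
    out = []
    for doc in docs:
        try:
            if report is not None:
                allowed = (
                    None if config.extractor.config.allow_all_type_pairs else DEFAULT_TYPE_PAIRS
                )
                report.pairs_generated += len(generate_pairs(group_entities(doc), allowed))
            relations = predict_relations(doc, config.extractor)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("extractor", doc.doc_id, exc) from exc
        if report is not None:
            report.relations_kept += len(relations)
        result = Document(doc.doc_id, doc.title, doc.abstract, mentions=list(doc.mentions))
        result.relations = relations
        out.append(result)
    return out


def run_pipeline(
    docs: Sequence[Document], config: PipelineConfig
) -> tuple[list[Document], RunReport]:
    """Raw documents in, fully annotated documents plus a run report out."""
    report = RunReport(n_docs=len(docs))
    t0 = time.perf_counter()
    tagged = tag_stage(docs, config)
    report.seconds_per_doc["tagger"] = (time.perf_counter() - t0) / max(len(docs), 1)
    report.mentions_tagged = sum(len(d.mentions) for d in tagged)
    t0 = time.perf_counter()
    linked = link_stage(tagged, config, report)
    report.seconds_per_doc["linker"] = (time.perf_counter() - t0) / max(len(docs), 1)
    t0 = time.perf_counter()
    final = extract_stage(linked, config, report)
    report.seconds_per_doc["extractor"] = (time.perf_counter() - t0) / max(len(docs), 1)
    logger.info("pipeline report: %s", report.as_dict())
    return final, report
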