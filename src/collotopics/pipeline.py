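"""End-to-end corpus → collocates → topics → theme-prevalence pipeline.

Orchestrates the stage modules: target-article selection, content-word
preprocessing, windowed collocate scoring with an MI shortlist, per-stratum
LDA fits (one model per region plus a pooled "ALL" model), and — when a
topic→theme mapping is supplied — theme-prevalence tables.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .collocates import (
    DEFAULT_MI_MIN,
    CollocateRecord,
    WindowSpec,
    records_to_frame,
    score_collocates,
    shortlist,
)
from .corpus_io import DEFAULT_TARGETS, Document, region_of, select_target_articles
from .preprocess import preprocess_text
from .themes import ThemeMapping, ThemePrevalence, prevalence_table, theme_prevalence
from .topic_model import LDAResults, build_bags, fit_lda

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stratum_seed"]


@dataclass
class PipelineConfig:
    """Tunable parameters of one pipeline run."""

    targets: frozenset[str] = DEFAULT_TARGETS
    window: WindowSpec = field(default_factory=WindowSpec)
    mi_min: float = DEFAULT_MI_MIN
    n_topics: int = 10
    alpha: float | None = None
    beta: float = 0.01
    n_iter: int = 1000
    burn_in: int = 500
    seed: int = 0
    stratify: bool = True
    tagger_backend: str = "rulebased"


@dataclass
class PipelineResult:
    """All per-stratum artifacts of a run, keyed by stratum name."""

    shortlists: dict[str, list[CollocateRecord]]
    lda: dict[str, LDAResults]
    n_selected: int
    n_read: int

    def collocate_frame(self) -> pd.DataFrame:
        frames = [records_to_frame(v) for v in self.shortlists.values()]
        return pd.concat(frames, ignore_index=True) if frames else records_to_frame([])

    def prevalence(
        self, mappings: Mapping[str, ThemeMapping], unit: str = "tokens"
    ) -> pd.DataFrame:
        rows: list[list[ThemePrevalence]] = []
        for stratum, results in self.lda.items():
            if stratum not in mappings:
                raise ValueError(f"no theme mapping supplied for stratum {stratum!r}")
            rows.append(theme_prevalence(results, mappings[stratum], unit=unit))
        return prevalence_table(rows)


def stratum_seed(base_seed: int, stratum: str) -> int:
    """Stable per-stratum seed derived from the run seed (below 2**31)."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(stratum.encode())) % (2**31)


def run_pipeline(docs: Sequence[Document], config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full analysis on an in-memory corpus.

    Strata are the five regions (documents grouped by the region of their
    country label) plus a pooled "ALL" stratum; with ``stratify=False`` only
    the pooled model is fitted. Strata whose shortlist or bags are empty
    are skipped with a log line.
    """
    selected = select_target_articles(docs, config.targets)
    annotated = [preprocess_text(d.text, backend=config.tagger_backend) for d in selected]
    meta = [{"doc_id": d.doc_id, "country": d.country} for d in selected]

    groups: dict[str, list[int]] = {"ALL": list(range(len(selected)))}
    if config.stratify:
        for i, d in enumerate(selected):
            groups.setdefault(region_of(d.country), []).append(i)

    shortlists: dict[str, list[CollocateRecord]] = {}
    lda: dict[str, LDAResults] = {}
    for stratum in sorted(groups):
        idx = groups[stratum]
        sub_docs = [annotated[i] for i in idx]
        sub_meta = [meta[i] for i in idx]
        records = score_collocates(
            sub_docs, config.targets, config.window, country=stratum
        )
        kept = shortlist(records, config.mi_min)
        if not kept:
            logger.warning("stratum %s: empty shortlist, skipping topic model", stratum)
            continue
        shortlists[stratum] = kept
        bags = build_bags(sub_docs, sub_meta, kept, config.targets, config.window)
        if not bags.nonempty():
            logger.warning("stratum %s: no non-empty bags, skipping topic model", stratum)
            continue
        lda[stratum] = fit_lda(
            bags,
            K=config.n_topics,
            alpha=config.alpha,
            beta=config.beta,
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            seed=stratum_seed(config.seed, stratum),
        )
    return PipelineResult(
        shortlists=shortlists, lda=lda, n_selected=len(selected), n_read=len(docs)
    )
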