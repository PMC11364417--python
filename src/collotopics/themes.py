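"""Topic → theme mapping and theme-prevalence estimation per stratum.

Topics are fitted word distributions; themes are human-assigned labels
grouping one or more topics (the canonical label set for pregnancy
narratives: complications_risk, crime, celebration, celebrity_births,
contraception, plus a residual "other"). The package never auto-labels
real corpora: the mapping is supplied as an editable config file keyed by
stratum and topic id. Prevalence of a theme in a stratum is the share of
fitted collocate tokens whose final topic assignment carries that theme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .topic_model import LDAResults

__all__ = [
    "STANDARD_THEMES",
    "ThemeMapping",
    "ThemePrevalence",
    "theme_prevalence",
    "prevalence_table",
    "pooled_prevalence",
    "labeling_report",
    "load_theme_mapping",
    "save_theme_mapping",
    "plot_prevalence",
]

#: The five canonical narrative themes plus the residual label.
STANDARD_THEMES = (
    "complications_risk",
    "crime",
    "celebration",
    "celebrity_births",
    "contraception",
    "other",
)


@dataclass(frozen=True)
class ThemeMapping:
    """Assignment of every topic of one stratum's model to a theme label."""

    stratum: str
    entries: Mapping[int, str] = field(default_factory=dict)

    def complete(self, n_topics: int) -> "ThemeMapping":
        """Fill unlabeled topics with the residual label 'other'."""
        full = {k: self.entries.get(k, "other") for k in range(n_topics)}
        return ThemeMapping(self.stratum, full)

    def themes(self) -> list[str]:
        ordered = [t for t in STANDARD_THEMES if t in set(self.entries.values())]
        extra = sorted(set(self.entries.values()) - set(STANDARD_THEMES))
        return ordered + extra


@dataclass(frozen=True)
class ThemePrevalence:
    """Share (percent) of one theme's tokens within one stratum."""

    stratum: str
    theme: str
    share: float
    token_count: int


def theme_prevalence(
    results: LDAResults,
    mapping: ThemeMapping,
    unit: str = "tokens",
) -> list[ThemePrevalence]:
    """Compute per-theme prevalence for one stratum's fitted model.

    ``unit="tokens"`` (default): each fitted token contributes its final
    topic assignment's theme; the share is 100 × theme tokens / total
    tokens. ``unit="documents"`` is a sensitivity alternative where each
    fitted document contributes once, to its dominant theme.
    """
    K = results.K
    uncovered = [k for k in range(K) if k not in mapping.entries]
    if uncovered:
        raise ValueError(
            f"theme mapping for stratum {mapping.stratum!r} does not cover "
            f"topic_ids {uncovered}; label them or call mapping.complete(K)"
        )
    themes = mapping.themes()
    if "other" not in themes:
        themes = themes + ["other"]
    theme_index = {t: i for i, t in enumerate(themes)}
    counts = np.zeros(len(themes), dtype=np.int64)

    if unit == "tokens":
        per_topic = results.n_k
        for k in range(K):
            counts[theme_index[mapping.entries[k]]] += int(per_topic[k])
    elif unit == "documents":
        theta = results.theta
        for d in results.model.bags.nonempty():
            dominant = int(np.argmax(theta[d]))
            counts[theme_index[mapping.entries[dominant]]] += 1
    else:
        raise ValueError("unit must be 'tokens' or 'documents'")

    total = counts.sum()
    out = []
    for t in themes:
        c = int(counts[theme_index[t]])
        share = 100.0 * c / total if total else 0.0
        out.append(ThemePrevalence(mapping.stratum, t, share, c))
    return out


def pooled_prevalence(per_stratum: Sequence[Sequence[ThemePrevalence]]) -> list[ThemePrevalence]:
    """Pool strata into an "ALL" row by concatenating token counts.

    Equivalent to the token-count-weighted mean of stratum shares.
    """
    counts: dict[str, int] = {}
    for rows in per_stratum:
        for r in rows:
            counts[r.theme] = counts.get(r.theme, 0) + r.token_count
    total = sum(counts.values())
    ordered = [t for t in STANDARD_THEMES if t in counts] + sorted(
        set(counts) - set(STANDARD_THEMES)
    )
    return [
        ThemePrevalence("ALL", t, 100.0 * counts[t] / total if total else 0.0, counts[t])
        for t in ordered
    ]


def prevalence_table(per_stratum: Sequence[Sequence[ThemePrevalence]]) -> pd.DataFrame:
    """Long-format table (stratum, theme, share_pct, token_count)."""
    rows = [
        {"stratum": r.stratum, "theme": r.theme, "share_pct": r.share, "token_count": r.token_count}
        for stratum_rows in per_stratum
        for r in stratum_rows
    ]
    return pd.DataFrame(rows, columns=["stratum", "theme", "share_pct", "token_count"])


def labeling_report(
    results: LDAResults, top_k: int = 20, n_exemplars: int = 10
) -> dict:
    """The human-labeling report: per topic, top words and exemplar documents.

    Exemplars are the documents with the highest estimated topic share
    (ties broken by doc_id); documents with empty bags never appear. No
    automatic labels are produced — labeling is a human step.
    """
    theta = results.theta
    meta = results.model.bags.doc_meta
    nonempty = results.model.bags.nonempty()
    report = {}
    for k in range(results.K):
        scored = sorted(
            ((float(theta[d, k]), str(meta[d]["doc_id"])) for d in nonempty),
            key=lambda s: (-s[0], s[1]),
        )
        report[k] = {
            "top_words": results.top_words(k, top_k).top_words,
            "exemplars": [
                {"doc_id": doc_id, "topic_share": share}
                for share, doc_id in scored[:n_exemplars]
            ],
        }
    return report


def labeling_report_text(results: LDAResults, top_k: int = 20, n_exemplars: int = 10) -> str:
    rep = labeling_report(results, top_k, n_exemplars)
    lines = []
    for k, entry in rep.items():
        lines.append(f"topic {k}")
        lines.append("  words: " + ", ".join(w for w, _ in entry["top_words"]))
        lines.append(
            "  exemplars: "
            + ", ".join(f"{e['doc_id']} ({e['topic_share']:.2f})" for e in entry["exemplars"])
        )
    return "\n".join(lines)


def load_theme_mapping(path: str | Path, n_topics: int | None = None) -> dict[str, ThemeMapping]:
    """Load a YAML mapping file keyed by stratum, then topic_id -> label.

    When ``n_topics`` is given, unlabeled topics default to "other".
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    out = {}
    for stratum, entries in raw.items():
        m = ThemeMapping(str(stratum), {int(k): str(v) for k, v in (entries or {}).items()})
        out[str(stratum)] = m.complete(n_topics) if n_topics is not None else m
    return out


def save_theme_mapping(mappings: Sequence[ThemeMapping], path: str | Path) -> None:
    data = {m.stratum: {int(k): v for k, v in sorted(m.entries.items())} for m in mappings}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def plot_prevalence(table: pd.DataFrame, path: str | Path | None = None):
    """Stacked-bar chart of theme shares by stratum (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot(index="stratum", columns="theme", values="share_pct").fillna(0.0)
    cols = [t for t in STANDARD_THEMES if t in pivot.columns] + [
        c for c in pivot.columns if c not in STANDARD_THEMES
    ]
    pivot = pivot[cols]
    ax = pivot.plot(kind="bar", stacked=True, figsize=(8, 4.5), width=0.7)
    ax.set_ylabel("share of collocate tokens (%)")
    ax.set_xlabel("")
    ax.legend(bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=8)
    plt.tight_layout()
    if path is not None:
        plt.savefig(path)
        plt.close()
    return ax
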