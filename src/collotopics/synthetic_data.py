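"""Ground-truthed synthetic corpora emulating a multi-country news corpus.

Real multi-country news corpora are licensed and cannot ship with the
package, so every pipeline stage is exercised against generated corpora with
known structure instead. The generator inverts the analysis model: each
document belongs to a region, draws a narrative theme from that region's
theme weights, draws a topic mixture over the theme's topics, and emits
content tokens from per-topic word distributions. A target keyword
("pregnant" or "pregnancy") is inserted into a configurable fraction of
documents together with planted collocates from the theme's signature
vocabulary placed within the ±6-content-token window, and closed-class
function words are interleaved so the content filter has real work to do.

Documents are structured token streams sufficient to exercise the pipeline,
not readable prose. Everything is reproducible: a fixed seed yields a
byte-identical corpus, and the returned :class:`GroundTruth` records the
quantities the pipeline is expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus_io import Document, REGIONS
from .preprocess import FUNCTION_WORDS
from .themes import STANDARD_THEMES, ThemeMapping
from .topic_model import BagCorpus, LDAResults

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "DEFAULT_THEME_SIGNATURES",
    "DEFAULT_REGION_WEIGHTS",
    "generate",
    "truth_report",
    "sample_lda_corpus",
    "signature_theme_mapping",
]

#: Signature vocabulary per theme, drawn from reported high-probability
#: words for each narrative theme; used both as planted window collocates
#: and as topic-signature words so pipeline output is human-readable.
DEFAULT_THEME_SIGNATURES: dict[str, tuple[str, ...]] = {
    "complications_risk": (
        "complication", "risk", "difficult", "disease", "miscarriage",
        "ectopic", "eclampsia", "hypertension", "condition", "suffer",
    ),
    "crime": (
        "victim", "police", "rape", "kill", "murder", "shoot", "attack",
        "revenge", "arrest", "prosecution",
    ),
    "celebration": (
        "announce", "reveal", "share", "post", "couple", "celebrate",
        "joy", "family", "surprise", "gift",
    ),
    "celebrity_births": (
        "actress", "duchess", "prince", "royal", "baby", "star",
        "singer", "celebrity", "interview", "magazine",
    ),
    "contraception": (
        "contraception", "pill", "prevent", "unwanted", "unplanned",
        "abortion", "criminalise", "access", "clinic", "planning",
    ),
}

_BASE_WEIGHTS = (0.33, 0.27, 0.20, 0.13, 0.07)

#: Default per-region theme weights: distinct cyclic shifts of a base
#: vector whose adjacent gaps are all >= 6 percentage points, so each
#: region has a well-separated, distinguishable theme ranking.
DEFAULT_REGION_WEIGHTS: dict[str, dict[str, float]] = {
    region: {
        theme: _BASE_WEIGHTS[(j - i) % 5]
        for j, theme in enumerate(STANDARD_THEMES[:5])
    }
    for i, region in enumerate(sorted(REGIONS))
}

_TARGETS = ("pregnant", "pregnancy")


@dataclass
class GeneratorSpec:
    """Study-condition parameters of the synthetic corpus generator."""

    K: int = 10
    V_content: int = 200
    themes: Mapping[str, tuple[int, ...]] | None = None
    region_theme_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {r: dict(w) for r, w in DEFAULT_REGION_WEIGHTS.items()}
    )
    docs_per_region: int = 200
    doc_length_mean: float = 150.0
    alpha: float = 0.1
    phi_concentration: float = 0.05
    signature_mass: float = 0.0
    target_insertion_rate: float = 0.4
    function_word_rate: float = 0.45
    n_planted: int = 3
    soft_theme_mixture: bool = False
    quota_themes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.themes is None:
            # themes partition [0, K) into contiguous blocks, one per theme
            labels = list(self.region_theme_weights[next(iter(self.region_theme_weights))])
            bounds = np.linspace(0, self.K, len(labels) + 1).astype(int)
            self.themes = {
                lab: tuple(range(bounds[i], bounds[i + 1])) for i, lab in enumerate(labels)
            }
        self.validate()

    def validate(self) -> None:
        all_topics = sorted(t for ts in self.themes.values() for t in ts)
        if all_topics != list(range(self.K)):
            raise ValueError(
                f"themes must partition topics [0, {self.K}); got {self.themes}"
            )
        for region, weights in self.region_theme_weights.items():
            s = sum(weights.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"theme weights for {region} sum to {s}, not 1")
            if set(weights) != set(self.themes):
                raise ValueError(f"theme weights for {region} must cover {set(self.themes)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorSpec":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "themes" in raw and raw["themes"] is not None:
            raw["themes"] = {k: tuple(v) for k, v in raw["themes"].items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """Everything the pipeline is expected to recover from a generated corpus."""

    vocab: list[str]
    phi: np.ndarray
    theta: np.ndarray
    true_theme_shares: dict[str, dict[str, float]]
    seeded_target_docs: set[str]
    planted_collocate_pairs: set[tuple[str, str]]
    doc_themes: dict[str, str]
    content_tokens_by_doc: dict[str, list[str]]
    topic_theme: dict[int, str]

    def content_tally(self) -> dict[str, int]:
        """Corpus-wide emission counts of content lemmas (incl. targets)."""
        tally: dict[str, int] = {}
        for toks in self.content_tokens_by_doc.values():
            for t in toks:
                tally[t] = tally.get(t, 0) + 1
        return tally


def _make_phi(spec: GeneratorSpec, vocab: list[str], rng: np.random.Generator) -> np.ndarray:
    """Topic-word distributions over the synthetic content vocabulary.

    The Dirichlet base measure covers only the generic ``w####`` lemmas;
    signature words carry probability only through the explicit
    ``signature_mass`` boost, so with zero boost they are emitted solely as
    planted window collocates.
    """
    V = len(vocab)
    word_index = {w: i for i, w in enumerate(vocab)}
    generic = np.array([w.startswith("w") and w[1:].isdigit() for w in vocab])
    phi = np.zeros((spec.K, V))
    phi[:, generic] = rng.dirichlet(
        np.full(int(generic.sum()), spec.phi_concentration), size=spec.K
    )
    if spec.signature_mass > 0:
        for theme, topics in spec.themes.items():
            sig = [w for w in DEFAULT_THEME_SIGNATURES.get(theme, ()) if w in word_index]
            if not sig:
                continue
            boost = np.zeros(V)
            boost[[word_index[w] for w in sig]] = 1.0 / len(sig)
            for k in topics:
                phi[k] = (1 - spec.signature_mass) * phi[k] + spec.signature_mass * boost
    return phi / phi.sum(axis=1, keepdims=True)


def generate(
    spec: GeneratorSpec, seed: int | None = None
) -> tuple[list[Document], GroundTruth]:
    """Generate a synthetic corpus and its ground truth.

    Fixed seed (``spec.seed`` unless overridden) yields a byte-identical
    corpus. Regions are iterated in sorted name order, documents within a
    region in index order.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.Generator(np.random.PCG64(int(seed) % (2**31)))
    themes = list(spec.themes)
    regions = sorted(spec.region_theme_weights)

    vocab = [f"w{i:04d}" for i in range(spec.V_content)]
    sig_words = sorted(
        {w for t in themes for w in DEFAULT_THEME_SIGNATURES.get(t, ())}
    )
    vocab = sig_words + vocab
    phi = _make_phi(spec, vocab, rng)

    docs: list[Document] = []
    thetas: list[np.ndarray] = []
    seeded: set[str] = set()
    planted_pairs: set[tuple[str, str]] = set()
    doc_themes: dict[str, str] = {}
    content_by_doc: dict[str, list[str]] = {}

    for region in regions:
        weights = spec.region_theme_weights[region]
        wvec = np.array([weights[t] for t in themes])
        countries = sorted(REGIONS[region])
        if spec.quota_themes:
            # stratified allocation: the region's realized theme composition
            # equals its weight vector up to rounding (largest remainder),
            # like fixing per-arm sample sizes in a designed experiment
            exact = wvec * spec.docs_per_region
            counts = np.floor(exact).astype(int)
            rema = np.argsort(-(exact - counts))
            counts[rema[: spec.docs_per_region - counts.sum()]] += 1
            theme_seq = rng.permutation(np.repeat(np.arange(len(themes)), counts))
        else:
            theme_seq = rng.choice(len(themes), size=spec.docs_per_region, p=wvec)
        for i in range(spec.docs_per_region):
            doc_id = f"{region}-{i:05d}"
            theme = themes[int(theme_seq[i])]
            support = np.array(spec.themes[theme], dtype=int)
            theta = np.zeros(spec.K)
            if spec.soft_theme_mixture:
                theta_all = rng.dirichlet(np.full(spec.K, spec.alpha) + 0.0)
                tilt = np.full(spec.K, 0.05)
                tilt[support] = 1.0
                theta = theta_all * tilt
                theta /= theta.sum()
            else:
                theta[support] = rng.dirichlet(np.full(len(support), spec.alpha))
            L = max(10, int(rng.poisson(spec.doc_length_mean)))
            z = rng.choice(spec.K, size=L, p=theta)
            word_ids = np.empty(L, dtype=np.int64)
            for k in np.unique(z):
                sel = z == k
                word_ids[sel] = rng.choice(len(vocab), size=int(sel.sum()), p=phi[k])
            content = [vocab[w] for w in word_ids]

            if rng.random() < spec.target_insertion_rate:
                target = _TARGETS[int(rng.integers(2))]
                sig = list(DEFAULT_THEME_SIGNATURES.get(theme, ())) or ["w0000"]
                n_plant = min(spec.n_planted, len(sig))
                plant = list(rng.choice(sig, size=n_plant, replace=False))
                # contiguous block around the target guarantees every planted
                # collocate sits within ±6 content positions of it
                n_before = int(rng.integers(0, n_plant + 1))
                block = plant[:n_before] + [target] + plant[n_before:]
                ip = int(rng.integers(0, len(content) + 1))
                content = content[:ip] + block + content[ip:]
                seeded.add(doc_id)
                planted_pairs.update((target, w) for w in plant)

            # interleave function-word filler at the requested rate
            f = spec.function_word_rate
            lam = f / (1 - f) if f < 1 else 1.0
            n_fill = rng.poisson(lam, size=len(content))
            fillers = rng.integers(len(FUNCTION_WORDS), size=int(n_fill.sum()))
            out_tokens: list[str] = []
            fpos = 0
            for tok, nf in zip(content, n_fill):
                for _ in range(nf):
                    out_tokens.append(FUNCTION_WORDS[int(fillers[fpos])])
                    fpos += 1
                out_tokens.append(tok)

            country = countries[int(rng.integers(len(countries)))]
            month = int(rng.integers(1, 13))
            day = int(rng.integers(1, 29))
            docs.append(
                Document(
                    doc_id=doc_id,
                    date=f"2019-{month:02d}-{day:02d}",
                    title=f"synthetic article {doc_id}",
                    source=f"synthetic-news-{region.lower()}",
                    country=country,
                    text=" ".join(out_tokens),
                )
            )
            thetas.append(theta)
            doc_themes[doc_id] = theme
            content_by_doc[doc_id] = content

    truth = GroundTruth(
        vocab=vocab,
        phi=phi,
        theta=np.asarray(thetas) if thetas else np.zeros((0, spec.K)),
        true_theme_shares={r: dict(spec.region_theme_weights[r]) for r in regions},
        seeded_target_docs=seeded,
        planted_collocate_pairs=planted_pairs,
        doc_themes=doc_themes,
        content_tokens_by_doc=content_by_doc,
        topic_theme={k: t for t, ks in spec.themes.items() for k in ks},
    )
    return docs, truth


def truth_report(truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Tables of the generator's ground truth, for test comparison.

    Returns ``theme_shares`` (region, theme, true_share — shares sum to 1
    per region) and ``planted_pairs`` (target, collocate).
    """
    share_rows = [
        {"region": r, "theme": t, "true_share": s}
        for r, shares in sorted(truth.true_theme_shares.items())
        for t, s in shares.items()
    ]
    pair_rows = [
        {"target": a, "collocate": b} for a, b in sorted(truth.planted_collocate_pairs)
    ]
    return {
        "theme_shares": pd.DataFrame(share_rows, columns=["region", "theme", "true_share"]),
        "planted_pairs": pd.DataFrame(pair_rows, columns=["target", "collocate"]),
    }


def sample_lda_corpus(
    K: int = 5,
    V: int = 200,
    D: int = 500,
    doc_length_mean: float = 100.0,
    alpha: float = 0.1,
    phi_concentration: float = 0.05,
    seed: int = 0,
) -> tuple[BagCorpus, np.ndarray, np.ndarray]:
    """Sample a bag corpus directly from the LDA generative model.

    Used for estimator-recovery checks: returns the corpus together with
    the true topic-word matrix phi (K×V) and document mixtures theta (D×K).
    """
    rng = np.random.Generator(np.random.PCG64(int(seed) % (2**31)))
    vocab = [f"w{i:04d}" for i in range(V)]
    phi = rng.dirichlet(np.full(V, phi_concentration), size=K)
    theta = rng.dirichlet(np.full(K, alpha), size=D)
    docs = []
    for d in range(D):
        L = max(1, int(rng.poisson(doc_length_mean)))
        z = rng.choice(K, size=L, p=theta[d])
        w = [int(rng.choice(V, p=phi[k])) for k in z]
        docs.append(w)
    meta = [{"doc_id": f"d{d:05d}"} for d in range(D)]
    return BagCorpus(vocab, docs, meta), phi, theta


def signature_theme_mapping(
    results: LDAResults,
    stratum: str = "ALL",
    signatures: Mapping[str, Sequence[str]] = DEFAULT_THEME_SIGNATURES,
    min_mass: float = 0.0,
) -> ThemeMapping:
    """Ground-truth-based topic→theme mapping for generated corpora.

    Assigns each fitted topic the theme whose signature words carry the
    most probability mass in that topic (topics below ``min_mass`` fall to
    "other"). This is an evaluation helper for synthetic corpora with known
    signature vocabularies — not an auto-labeler for real data.
    """
    vocab_index = {w: i for i, w in enumerate(results.model.bags.vocab)}
    phi = results.phi
    entries = {}
    theme_list = sorted(signatures)
    for k in range(results.K):
        masses = []
        for theme in theme_list:
            idx = [vocab_index[w] for w in signatures[theme] if w in vocab_index]
            masses.append(phi[k, idx].sum() if idx else 0.0)
        best = int(np.argmax(masses))
        entries[k] = theme_list[best] if masses[best] > min_mass else "other"
    return ThemeMapping(stratum, entries)
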