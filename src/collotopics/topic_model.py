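"""Latent Dirichlet Allocation fitted by collapsed Gibbs sampling.

The model: each document d mixes K topics with weights θ_d ~ Dirichlet(α),
each topic k is a distribution φ_k over the vocabulary with
φ_k ~ Dirichlet(β), and every token draws a topic z ~ θ_d then a word
w ~ φ_z. The sampler integrates θ and φ out and resamples each token's
topic from its full conditional

    p(z_i = k | z_-i, w) ∝ (n_dk + α) (n_kw + β) / (n_k + V β)

where the counts exclude token i. The API follows the model/results
convention: :class:`LatentDirichletAllocation` is constructed from a
:class:`BagCorpus` and ``fit()`` returns an :class:`LDAResults` carrying the
final count tables, assignments, diagnostics, and reporting helpers.

Determinism contract: a fixed seed yields a bit-identical final state, and
documents are processed in a canonical order (sorted by doc_id), so
permuting the input document order changes nothing but the row order of
document-indexed outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .collocates import CollocateRecord, WindowSpec
from .corpus_io import region_of
from .preprocess import AnnotatedToken

logger = logging.getLogger(__name__)

__all__ = [
    "BagCorpus",
    "TopicSummary",
    "LatentDirichletAllocation",
    "LDAResults",
    "build_bags",
    "fit_lda",
    "log_likelihood",
    "match_topics",
]


@dataclass
class BagCorpus:
    """Bag-of-words corpus over a fixed vocabulary.

    ``docs[d]`` lists vocabulary indices (with multiplicity) of document d's
    retained tokens; ``doc_meta`` carries parallel per-document metadata
    (at least ``doc_id``; optionally ``country`` and ``region``). Documents
    with empty bags are recorded but excluded from fitting.
    """

    vocab: list[str]
    docs: list[list[int]]
    doc_meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.vocab:
            raise ValueError("BagCorpus requires a non-empty vocabulary")
        V = len(self.vocab)
        for d, bag in enumerate(self.docs):
            for w in bag:
                if not 0 <= w < V:
                    raise ValueError(f"doc {d}: vocab index {w} out of range [0, {V})")
        if not self.doc_meta:
            self.doc_meta = [{"doc_id": f"d{d}"} for d in range(len(self.docs))]
        if len(self.doc_meta) != len(self.docs):
            raise ValueError("doc_meta must parallel docs")

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def n_words(self) -> int:
        return len(self.vocab)

    @property
    def n_tokens(self) -> int:
        return sum(len(b) for b in self.docs)

    def nonempty(self) -> list[int]:
        return [d for d, bag in enumerate(self.docs) if bag]


@dataclass(frozen=True)
class TopicSummary:
    """Ranked top words of one topic with smoothed probabilities."""

    topic_id: int
    top_words: list[tuple[str, float]]


def build_bags(
    annotated_docs: Sequence[Sequence[AnnotatedToken]],
    meta: Sequence[Mapping],
    shortlisted: Sequence[CollocateRecord] | Iterable[str],
    targets: Iterable[str],
    window: WindowSpec = WindowSpec(),
) -> BagCorpus:
    """Build the LDA input: per-document bags of shortlisted window collocates.

    A document's bag is its content-stream tokens restricted to shortlisted
    lemmas lying within ±half_width content positions of a target occurrence
    in that same document; target lemmas themselves are excluded. Documents
    left with an empty bag are kept in the corpus (and logged) but will not
    enter fitting.
    """
    shortlist_lemmas = [
        r.lemma if isinstance(r, CollocateRecord) else str(r) for r in shortlisted
    ]
    if not shortlist_lemmas:
        raise ValueError("shortlist must be non-empty")
    target_set = frozenset(targets)
    vocab = sorted(set(shortlist_lemmas) - target_set)
    index = {w: i for i, w in enumerate(vocab)}
    h = window.half_width

    bags: list[list[int]] = []
    doc_meta: list[dict] = []
    n_empty = 0
    for doc, m in zip(annotated_docs, meta):
        lemmas = [t.lemma for t in doc if t.is_content] if window.stream == "content" else [
            t.lemma for t in doc
        ]
        covered = np.zeros(len(lemmas), dtype=bool)
        for p, lemma in enumerate(lemmas):
            if lemma in target_set:
                covered[max(0, p - h) : p + h + 1] = True
                covered[p] = False
        bag = [
            index[lemma]
            for p, lemma in enumerate(lemmas)
            if covered[p] and lemma in index
        ]
        if not bag:
            n_empty += 1
        bags.append(bag)
        entry = {"doc_id": str(m["doc_id"])}
        if "country" in m and m["country"]:
            entry["country"] = m["country"]
            entry["region"] = region_of(m["country"])
        doc_meta.append(entry)
    if n_empty:
        logger.info("build_bags: %d of %d documents have empty bags (excluded from fitting)", n_empty, len(bags))
    return BagCorpus(vocab=vocab, docs=bags, doc_meta=doc_meta)


# ---------------------------------------------------------------------------
# Gibbs kernel


@njit(cache=True)
def _sample_token(d, w, k_old, n_kw, n_dk, n_k, alpha, beta, u):
    """Resample one token's topic from its full conditional; returns k_new.

    Decrements the token's own counts, samples k ∝ (n_dk+α)(n_kw+β)/(n_k+Vβ)
    by inverse CDF on the uniform ``u``, and re-increments.
    """
    K, V = n_kw.shape
    n_kw[k_old, w] -= 1
    n_dk[d, k_old] -= 1
    n_k[k_old] -= 1
    total = 0.0
    cum = np.empty(K, dtype=np.float64)
    for k in range(K):
        p = (n_dk[d, k] + alpha) * (n_kw[k, w] + beta) / (n_k[k] + V * beta)
        total += p
        cum[k] = total
    r = u * total
    k_new = K - 1
    for k in range(K):
        if r < cum[k]:
            k_new = k
            break
    n_kw[k_new, w] += 1
    n_dk[d, k_new] += 1
    n_k[k_new] += 1
    return k_new


@njit(cache=True)
def _sweep(doc_ids, word_ids, z, n_kw, n_dk, n_k, alpha, beta, us):
    for i in range(doc_ids.shape[0]):
        z[i] = _sample_token(
            doc_ids[i], word_ids[i], z[i], n_kw, n_dk, n_k, alpha, beta, us[i]
        )


def _collapsed_log_likelihood(n_kw, n_dk, alpha, beta, doc_lengths):
    K, V = n_kw.shape
    ll = 0.0
    # document side: prod_d DirMult(n_d. | alpha)
    ll += len(doc_lengths) * (gammaln(K * alpha) - K * gammaln(alpha))
    ll += gammaln(n_dk + alpha).sum() - gammaln(np.asarray(doc_lengths) + K * alpha).sum()
    # topic side: prod_k DirMult(n_k. | beta)
    n_k = n_kw.sum(axis=1)
    ll += K * (gammaln(V * beta) - V * gammaln(beta))
    ll += gammaln(n_kw + beta).sum() - gammaln(n_k + V * beta).sum()
    return float(ll)


class LatentDirichletAllocation:
    """LDA model over a :class:`BagCorpus`.

    Parameters
    ----------
    bags
        The bag-of-words corpus (documents with empty bags are excluded
        from fitting automatically).
    n_topics
        Number of topics K (default 10, matching ten topics per stratum).
    alpha
        Symmetric document-topic prior; default 50/K.
    beta
        Symmetric topic-word prior; default 0.01.
    """

    def __init__(
        self,
        bags: BagCorpus,
        n_topics: int = 10,
        alpha: float | None = None,
        beta: float = 0.01,
    ):
        if n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if alpha is None:
            alpha = 50.0 / n_topics
        if alpha <= 0 or beta <= 0:
            raise ValueError("priors alpha and beta must be positive")
        if not bags.nonempty():
            raise ValueError("corpus has no non-empty documents to fit")
        self.bags = bags
        self.K = int(n_topics)
        self.alpha = float(alpha)
        self.beta = float(beta)

    @classmethod
    def from_dataframe(
        cls, frame, vocab: Sequence[str] | None = None, token_col: str = "lemma",
        doc_col: str = "doc_id", **kwargs
    ) -> "LatentDirichletAllocation":
        """Build the model from a long-format token table (doc_id, lemma)."""
        if vocab is None:
            vocab = sorted(frame[token_col].unique())
        index = {w: i for i, w in enumerate(vocab)}
        docs, meta = [], []
        for doc_id, grp in frame.groupby(doc_col, sort=True):
            docs.append([index[w] for w in grp[token_col] if w in index])
            meta.append({"doc_id": str(doc_id)})
        return cls(BagCorpus(list(vocab), docs, meta), **kwargs)

    def fit(
        self,
        n_iter: int = 1000,
        burn_in: int = 500,
        seed: int = 0,
        n_restarts: int = 1,
    ) -> "LDAResults":
        """Run collapsed Gibbs sampling and return the fitted results.

        The point estimate is the final state after ``n_iter`` sweeps
        (``burn_in`` only marks where the log-likelihood trace is considered
        stationary; no averaging is done). Count-table invariants hold after
        every sweep.

        ``n_restarts > 1`` runs that many independently seeded chains and
        keeps the one with the highest final collapsed log-likelihood —
        the usual guard against a chain settling in a topic-merged local
        mode. Restart seeds are derived deterministically from ``seed``,
        so the whole procedure remains bit-reproducible.
        """
        if n_restarts > 1:
            fits = [
                self.fit(n_iter=n_iter, burn_in=burn_in,
                         seed=(int(seed) + 7_919 * r) % (2**31))
                for r in range(n_restarts)
            ]
            return max(fits, key=lambda f: f.log_likelihood())
        if n_iter <= burn_in or burn_in < 0:
            raise ValueError("need n_iter > burn_in >= 0")
        bags, K, V = self.bags, self.K, self.bags.n_words
        # canonical document order: sorted by (doc_id, input index)
        order = sorted(range(bags.n_docs), key=lambda d: (bags.doc_meta[d]["doc_id"], d))
        fit_docs = [d for d in order if bags.docs[d]]

        doc_ids = np.concatenate(
            [np.full(len(bags.docs[d]), i, dtype=np.int64) for i, d in enumerate(fit_docs)]
        ) if fit_docs else np.empty(0, dtype=np.int64)
        word_ids = np.concatenate(
            [np.asarray(bags.docs[d], dtype=np.int64) for d in fit_docs]
        ) if fit_docs else np.empty(0, dtype=np.int64)
        n_tokens = word_ids.shape[0]

        # one RNG stream consumed in canonical document order, so results
        # are invariant to the input ordering of documents
        rng = np.random.Generator(np.random.PCG64(int(seed) % (2**31)))
        z = rng.integers(0, K, size=n_tokens, dtype=np.int64)
        n_kw = np.zeros((K, V), dtype=np.int64)
        n_dk = np.zeros((len(fit_docs), K), dtype=np.int64)
        np.add.at(n_kw, (z, word_ids), 1)
        np.add.at(n_dk, (doc_ids, z), 1)
        n_k = n_kw.sum(axis=1)

        doc_lengths = np.asarray([len(bags.docs[d]) for d in fit_docs], dtype=np.int64)
        trace = []
        for sweep in range(n_iter):
            us = rng.random(n_tokens)
            _sweep(doc_ids, word_ids, z, n_kw, n_dk, n_k, self.alpha, self.beta, us)
            trace.append(
                _collapsed_log_likelihood(n_kw, n_dk, self.alpha, self.beta, doc_lengths)
            )

        # deterministic post-hoc topic ordering: by descending topic size,
        # ties by original index (handles label switching across runs/seeds
        # only in the sense of a canonical presentation order)
        topic_order = sorted(range(K), key=lambda k: (-int(n_k[k]), k))
        relabel = np.empty(K, dtype=np.int64)
        for new, old in enumerate(topic_order):
            relabel[old] = new
        z = relabel[z]
        n_kw = n_kw[topic_order]
        n_dk = n_dk[:, topic_order]
        n_k = n_k[topic_order]

        # map document-indexed outputs back to input order (empty docs: zero rows)
        full_n_dk = np.zeros((bags.n_docs, K), dtype=np.int64)
        z_by_doc: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * bags.n_docs
        offset = 0
        for i, d in enumerate(fit_docs):
            L = doc_lengths[i]
            full_n_dk[d] = n_dk[i]
            z_by_doc[d] = z[offset : offset + L].copy()
            offset += L

        return LDAResults(
            model=self,
            z_by_doc=z_by_doc,
            n_kw=n_kw,
            n_dk=full_n_dk,
            n_k=n_k,
            seed=int(seed),
            iterations_run=n_iter,
            burn_in=burn_in,
            loglik_trace=np.asarray(trace),
        )


def fit_lda(
    bags: BagCorpus,
    K: int = 10,
    alpha: float | None = None,
    beta: float = 0.01,
    n_iter: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
    n_restarts: int = 1,
) -> "LDAResults":
    """Functional wrapper: fit LDA on a bag corpus by collapsed Gibbs."""
    return LatentDirichletAllocation(bags, n_topics=K, alpha=alpha, beta=beta).fit(
        n_iter=n_iter, burn_in=burn_in, seed=seed, n_restarts=n_restarts
    )


@dataclass
class LDAResults:
    """Fitted LDA state: counts, assignments, diagnostics, reporting.

    Count identities (checked by ``validate()``): topic-word rows sum to the
    per-topic totals; document-topic rows sum to document lengths; topic
    totals sum to the token count.
    """

    model: LatentDirichletAllocation
    z_by_doc: list
    n_kw: np.ndarray
    n_dk: np.ndarray
    n_k: np.ndarray
    seed: int
    iterations_run: int
    burn_in: int
    loglik_trace: np.ndarray

    # -- estimates ---------------------------------------------------------
    @property
    def K(self) -> int:
        return self.model.K

    @property
    def phi(self) -> np.ndarray:
        """Smoothed topic-word distributions, shape (K, V)."""
        beta = self.model.beta
        return (self.n_kw + beta) / (self.n_k[:, None] + self.n_kw.shape[1] * beta)

    @property
    def theta(self) -> np.ndarray:
        """Smoothed document-topic distributions, shape (D, K)."""
        alpha = self.model.alpha
        lengths = self.n_dk.sum(axis=1, keepdims=True)
        return (self.n_dk + alpha) / (lengths + self.K * alpha)

    def validate(self) -> None:
        assert (self.n_kw.sum(axis=1) == self.n_k).all()
        lengths = np.asarray([len(b) for b in self.model.bags.docs])
        assert (self.n_dk.sum(axis=1) == lengths).all()
        assert self.n_k.sum() == lengths.sum()
        assert (self.n_kw >= 0).all() and (self.n_dk >= 0).all()

    def log_likelihood(self) -> float:
        """Collapsed joint log p(w, z | alpha, beta) of the final state."""
        lengths = [len(self.model.bags.docs[d]) for d in self.model.bags.nonempty()]
        n_dk = self.n_dk[self.model.bags.nonempty()]
        return _collapsed_log_likelihood(self.n_kw, n_dk, self.model.alpha, self.model.beta, lengths)

    def top_words(self, topic_id: int, k: int = 20) -> TopicSummary:
        """The k most probable words of a topic (ties broken lexicographically)."""
        if not 0 <= topic_id < self.K:
            raise ValueError(f"topic_id {topic_id} out of range [0, {self.K})")
        probs = self.phi[topic_id]
        vocab = self.model.bags.vocab
        ranked = sorted(zip(vocab, probs), key=lambda wp: (-wp[1], wp[0]))
        return TopicSummary(topic_id, [(w, float(p)) for w, p in ranked[:k]])

    # -- reporting ---------------------------------------------------------
    def summary(self, top_k: int = 10) -> str:
        bags = self.model.bags
        lines = [
            "Latent Dirichlet Allocation (collapsed Gibbs)",
            "=" * 46,
            f"Documents (fitted/total): {len(bags.nonempty())}/{bags.n_docs}",
            f"Vocabulary size:          {bags.n_words}",
            f"Tokens:                   {int(self.n_k.sum())}",
            f"Topics (K):               {self.K}",
            f"alpha / beta:             {self.model.alpha:g} / {self.model.beta:g}",
            f"Sweeps (burn-in):         {self.iterations_run} ({self.burn_in})",
            f"Seed:                     {self.seed}",
            f"Final log-likelihood:     {self.log_likelihood():.2f}",
            "",
        ]
        for k in range(self.K):
            words = ", ".join(w for w, _ in self.top_words(k, top_k).top_words)
            lines.append(f"topic {k:2d} (n={int(self.n_k[k])}): {words}")
        return "\n".join(lines)

    def top_words_frame(self, k: int = 20):
        import pandas as pd

        rows = []
        for t in range(self.K):
            for rank, (w, p) in enumerate(self.top_words(t, k).top_words, start=1):
                rows.append({"topic_id": t, "rank": rank, "lemma": w, "probability": p})
        return pd.DataFrame(rows)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "collotopics-lda-state-v1",
            "vocab": self.model.bags.vocab,
            "doc_meta": self.model.bags.doc_meta,
            "docs": [list(map(int, b)) for b in self.model.bags.docs],
            "K": self.K,
            "alpha": self.model.alpha,
            "beta": self.model.beta,
            "seed": self.seed,
            "iterations_run": self.iterations_run,
            "burn_in": self.burn_in,
            "z_by_doc": [list(map(int, z)) for z in self.z_by_doc],
            "n_kw": self.n_kw.tolist(),
            "n_dk": self.n_dk.tolist(),
            "n_k": self.n_k.tolist(),
            "loglik_trace": [float(x) for x in self.loglik_trace],
        }

    def save(self, path: str | Path) -> None:
        """Serialize the full state to a flat JSON file (exact inspection/resume)."""
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "LDAResults":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        if d.get("format") != "collotopics-lda-state-v1":
            raise ValueError("not a collotopics LDA state file")
        bags = BagCorpus(d["vocab"], [list(b) for b in d["docs"]], d["doc_meta"])
        model = LatentDirichletAllocation(bags, d["K"], d["alpha"], d["beta"])
        return cls(
            model=model,
            z_by_doc=[np.asarray(z, dtype=np.int64) for z in d["z_by_doc"]],
            n_kw=np.asarray(d["n_kw"], dtype=np.int64),
            n_dk=np.asarray(d["n_dk"], dtype=np.int64),
            n_k=np.asarray(d["n_k"], dtype=np.int64),
            seed=d["seed"],
            iterations_run=d["iterations_run"],
            burn_in=d["burn_in"],
            loglik_trace=np.asarray(d["loglik_trace"]),
        )


def log_likelihood(results: LDAResults, bags: BagCorpus | None = None) -> float:
    """Functional form of :meth:`LDAResults.log_likelihood`."""
    return results.log_likelihood()


def match_topics(phi_est: np.ndarray, phi_true: np.ndarray) -> tuple[np.ndarray, float]:
    """Align estimated topics with reference topics by Hungarian matching.

    Cost is 1 − cosine similarity between topic-word rows. Returns the
    permutation ``perm`` (``perm[j]`` = estimated topic matched to reference
    topic j) and the mean cosine similarity over matched pairs.
    """
    a = phi_est / np.linalg.norm(phi_est, axis=1, keepdims=True)
    b = phi_true / np.linalg.norm(phi_true, axis=1, keepdims=True)
    sim = b @ a.T
    rows, cols = linear_sum_assignment(1.0 - sim)
    return cols, float(sim[rows, cols].mean())
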