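"""Tokenization, POS tagging, lemmatization, and content-word filtering.

The cleaning stage mirrors standard corpus-linguistics practice for collocate
analysis: after lemmatization and POS tagging, only content-heavy words
(adjectives, nouns, verbs, adverbs) are retained; proper nouns, personal
pronouns, conjunctions, determiners, cardinals, and all forms of "have" and
"be" are removed.

Two tagger backends are defined. ``rulebased`` — the default — is a
deterministic suffix-plus-closed-class-lexicon tagger shipped with the
package, so the pipeline runs with no model download and annotation is
bit-reproducible. ``statistical`` delegates to spaCy when that library is
installed; selecting it without spaCy raises an error naming the fallback.

POS tags use a coarse universal tagset: ADJ, NOUN, PROPN, VERB, AUX, ADV,
PRON, DET, CONJ, NUM, OTHER. A token is a content word iff its tag is in
{ADJ, NOUN, VERB, ADV} and its lemma is not a form of "have"/"be".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "AnnotatedToken",
    "TAGSET",
    "CONTENT_POS",
    "FUNCTION_WORDS",
    "tokenize",
    "annotate",
    "content_stream",
    "preprocess_text",
]

TAGSET = frozenset(
    {"ADJ", "NOUN", "PROPN", "VERB", "AUX", "ADV", "PRON", "DET", "CONJ", "NUM", "OTHER"}
)

#: Tags retained by the content filter (configurable via ``keep_pos``).
CONTENT_POS = frozenset({"ADJ", "NOUN", "VERB", "ADV"})

_WORD_RE = re.compile(r"[a-z0-9]+(?:[-'’][a-z0-9]+)*")

# ---------------------------------------------------------------------------
# closed-class lexicons for the rule-based backend

_DETERMINERS = {
    "the", "a", "an", "this", "that", "these", "those", "each", "every",
    "some", "any", "no", "another", "such", "either", "neither", "both",
    "all", "several", "few", "many", "much", "enough",
}
_PRONOUNS = {
    "i", "you", "he", "she", "it", "we", "they", "me", "him", "her", "us",
    "them", "my", "your", "his", "its", "our", "their", "mine", "yours",
    "hers", "ours", "theirs", "myself", "yourself", "himself", "herself",
    "itself", "ourselves", "yourselves", "themselves", "who", "whom",
    "whose", "which", "what", "someone", "anyone", "everyone", "nobody",
    "somebody", "anybody", "everybody", "something", "anything",
    "everything", "nothing", "one", "ones", "other", "others",
}
_CONJUNCTIONS = {
    "and", "or", "but", "nor", "so", "yet", "because", "although", "though",
    "while", "whereas", "if", "unless", "until", "since", "when", "whenever",
    "where", "wherever", "whether", "than", "as",
}
_BE_FORMS = {"be", "am", "is", "are", "was", "were", "been", "being", "'s", "'re", "'m"}
_HAVE_FORMS = {"have", "has", "had", "having", "'ve", "'d"}
_MODALS = {"will", "would", "can", "could", "shall", "should", "may", "might", "must", "ought"}
_ADPOSITIONS = {
    "in", "on", "at", "by", "for", "with", "about", "against", "between",
    "into", "through", "during", "before", "after", "above", "below", "to",
    "from", "up", "down", "of", "off", "over", "under", "within", "without",
    "among", "across", "behind", "beyond", "near", "toward", "towards",
    "upon", "via", "per", "amid", "despite", "not", "n't", "there",
}
#: Number words are tagged ADJ (attributive quantifiers) and therefore kept;
#: digit strings are tagged NUM and removed. See the methods note for the
#: rationale behind this split.
_NUMBER_WORDS = {
    "one", "two", "three", "four", "five", "six", "seven", "eight", "nine",
    "ten", "eleven", "twelve", "thirteen", "fourteen", "fifteen", "sixteen",
    "seventeen", "eighteen", "nineteen", "twenty", "thirty", "forty",
    "fifty", "sixty", "seventy", "eighty", "ninety", "hundred", "thousand",
    "million", "billion",
}
_ADVERBS = {
    "very", "also", "too", "now", "then", "here", "often", "again", "never",
    "always", "soon", "already", "still", "just", "even", "only", "quite",
    "rather", "almost", "nearly", "together", "instead", "however",
    "perhaps", "maybe", "more", "most", "less", "least", "well",
}
_ADJ_LEXICON = {
    "pregnant", "new", "old", "good", "bad", "high", "low", "big", "small",
    "great", "difficult", "healthy", "unwanted", "unplanned", "royal",
    "ectopic", "severe", "several", "last", "first", "second", "third",
    "same", "own", "public", "medical", "maternal",
}
_VERB_LEXICON = {
    "use", "bring", "occur", "go", "do", "say", "get", "make", "know",
    "take", "see", "come", "give", "tell", "become", "show", "leave",
    "feel", "put", "mean", "keep", "let", "begin", "seem", "risk",
    "report", "face", "announce", "reveal", "share", "prevent", "kill",
}

#: Irregular lemma table; regular inflection is handled by suffix rules.
_IRREGULAR_LEMMAS = {
    "women": "woman", "children": "child", "men": "man", "people": "person",
    "feet": "foot", "teeth": "tooth", "mice": "mouse", "wives": "wife",
    "lives": "life", "babies": "baby",
    "was": "be", "were": "be", "is": "be", "are": "be", "am": "be",
    "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "told": "tell", "said": "say", "went": "go", "gone": "go", "did": "do",
    "does": "do", "done": "do", "made": "make", "got": "get", "gave": "give",
    "took": "take", "taken": "take", "saw": "see", "seen": "see",
    "came": "come", "knew": "know", "known": "know", "became": "become",
    "began": "begin", "begun": "begin", "left": "leave", "felt": "feel",
    "kept": "keep", "met": "meet", "found": "find", "brought": "bring",
    "thought": "think", "held": "hold", "born": "bear", "led": "lead",
    "bring": "bring", "sing": "sing", "thing": "thing", "king": "king",
    "during": "during", "including": "include", "according": "accord",
    "suffering": "suffer", "use": "use", "used": "use", "using": "use",
    # lexicalized participles/gerunds kept as their own lemmas
    "unwanted": "unwanted", "unplanned": "unplanned", "planning": "planning",
}

#: Closed-class filler vocabulary, exported for the synthetic-corpus
#: generator so filtering has realistic work to do. Clitic forms ("'s")
#: are excluded: as free-standing filler they would not tokenize whole.
FUNCTION_WORDS: tuple[str, ...] = tuple(
    sorted(
        w
        for w in (
            _DETERMINERS
            | _PRONOUNS
            | _CONJUNCTIONS
            | _BE_FORMS
            | _HAVE_FORMS
            | _MODALS
            | (_ADPOSITIONS - {"there"})
        )
        if "'" not in w
    )
)

_DIGIT_RE = re.compile(r"^\d+(?:[.,]\d+)*(?:st|nd|rd|th)?$")
_VOWELS = "aeiou"


@dataclass(frozen=True)
class AnnotatedToken:
    """A token with its lemma, coarse POS tag, and content-word flag.

    ``position_raw`` indexes the raw token stream; ``position_content`` is
    assigned consecutively over a document's content tokens by
    :func:`content_stream` and is ``None`` for non-content tokens.
    """

    surface: str
    lemma: str
    pos: str
    is_content: bool
    position_raw: int
    position_content: int | None = None


def tokenize(text: str) -> list[str]:
    """Split text into lowercased word tokens.

    Deterministic: words are maximal runs of alphanumerics with internal
    hyphens/apostrophes kept ("abortion-related" is one token); edge
    punctuation and all separators are dropped.
    """
    return _WORD_RE.findall(text.lower())


def _lemmatize(token: str, pos: str) -> str:
    if token in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[token]
    w = token
    if pos in {"NOUN", "PROPN"} or (pos == "VERB" and w.endswith("s")):
        if w.endswith("ies") and len(w) > 4:
            return w[:-3] + "y"
        if w.endswith(("ses", "xes", "zes", "ches", "shes")) and len(w) > 4:
            return w[:-2]
        if w.endswith("s") and not w.endswith(("ss", "us", "is")) and len(w) > 3:
            return w[:-1]
        return w
    if pos in {"VERB", "ADJ"}:
        if w.endswith("ied") and len(w) > 4:
            return w[:-3] + "y"
        if w.endswith("ed") and len(w) > 4:
            stem = w[:-2]
            if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS + "sl":
                return stem[:-1]
            # restore a silent 'e' (announced -> announce, criminalised ->
            # criminalise); heuristic on the stem-final letter
            if stem[-1] in "cvuzg" or stem.endswith(("is", "at", "iz", "os", "ir")):
                return stem + "e"
            return stem
        if w.endswith("ing") and len(w) > 5:
            stem = w[:-3]
            if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS + "sl":
                return stem[:-1]
            if stem[-1] in "cvuzg" or stem.endswith(("is", "at", "iz", "os", "ir")):
                return stem + "e"
            return stem
    return w


def _tag_one(token: str, surface: str) -> str:
    if _DIGIT_RE.match(token):
        return "NUM"
    if token in _BE_FORMS or token in _HAVE_FORMS:
        return "AUX"
    if token in _MODALS:
        return "AUX"
    if token in _DETERMINERS:
        return "DET"
    if token in _PRONOUNS:
        return "PRON"
    if token in _CONJUNCTIONS:
        return "CONJ"
    if token in _ADPOSITIONS:
        return "OTHER"
    if token in _NUMBER_WORDS:
        return "ADJ"
    if surface[:1].isupper():
        # capitalized open-class token: treated as a proper noun (the
        # removal rule is tag-driven, not gazetteer-driven)
        return "PROPN"
    if token in _ADVERBS or token.endswith("ly"):
        return "ADV"
    if token in _ADJ_LEXICON:
        return "ADJ"
    if token in _VERB_LEXICON or token in _IRREGULAR_LEMMAS and _IRREGULAR_LEMMAS[token] in _VERB_LEXICON:
        return "VERB"
    if token.endswith(("ed", "ing")) and len(token) > 4 and token not in _IRREGULAR_LEMMAS:
        return "VERB"
    if token.endswith(("ous", "ful", "ive", "able", "ible", "ical", "less", "ish")):
        return "ADJ"
    return "NOUN"


def _annotate_rulebased(raw_tokens: Sequence[str], surfaces: Sequence[str]) -> list[AnnotatedToken]:
    out = []
    for i, (tok, surf) in enumerate(zip(raw_tokens, surfaces)):
        pos = _tag_one(tok, surf)
        lemma = _lemmatize(tok, pos)
        is_content = pos in CONTENT_POS and lemma not in {"have", "be"}
        out.append(AnnotatedToken(surf, lemma, pos, is_content, i))
    return out


def annotate(
    tokens: Sequence[str],
    surfaces: Sequence[str] | None = None,
    backend: str = "rulebased",
    keep_pos: Iterable[str] = CONTENT_POS,
) -> list[AnnotatedToken]:
    """Annotate raw tokens with lemma, POS, and content-word flag.

    Parameters
    ----------
    tokens
        Lowercased tokens from :func:`tokenize`.
    surfaces
        Original-case forms (used for proper-noun detection); defaults to
        the tokens themselves.
    backend
        ``rulebased`` (default, shipped) or ``statistical`` (spaCy, if
        installed).
    """
    if surfaces is None:
        surfaces = tokens
    if len(surfaces) != len(tokens):
        raise ValueError("surfaces must parallel tokens")
    keep = frozenset(keep_pos)
    if backend == "rulebased":
        annotated = _annotate_rulebased(tokens, surfaces)
    elif backend == "statistical":
        try:
            import spacy  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "the statistical tagger backend requires spaCy "
                "(pip install spacy && python -m spacy download en_core_web_sm); "
                "use backend='rulebased' for the shipped deterministic tagger"
            ) from exc
        annotated = _annotate_spacy(tokens, surfaces)
    else:
        raise ValueError(f"unknown tagger backend {backend!r}")
    if keep != CONTENT_POS:
        annotated = [
            replace(t, is_content=t.pos in keep and t.lemma not in {"have", "be"})
            for t in annotated
        ]
    return annotated


def _annotate_spacy(tokens: Sequence[str], surfaces: Sequence[str]) -> list[AnnotatedToken]:
    import spacy

    nlp = spacy.load("en_core_web_sm", disable=["parser", "ner"])
    # spaCy's fine/universal tags mapped onto the coarse tagset
    posmap = {
        "ADJ": "ADJ", "NOUN": "NOUN", "PROPN": "PROPN", "VERB": "VERB",
        "AUX": "AUX", "ADV": "ADV", "PRON": "PRON", "DET": "DET",
        "CCONJ": "CONJ", "SCONJ": "CONJ", "NUM": "NUM",
    }
    doc = spacy.tokens.Doc(nlp.vocab, words=list(surfaces))
    for _, proc in nlp.pipeline:
        doc = proc(doc)
    out = []
    for i, t in enumerate(doc):
        pos = posmap.get(t.pos_, "OTHER")
        lemma = t.lemma_.lower()
        is_content = pos in CONTENT_POS and lemma not in {"have", "be"}
        out.append(AnnotatedToken(surfaces[i], lemma, pos, is_content, i))
    return out


def content_stream(annotated: Sequence[AnnotatedToken]) -> list[AnnotatedToken]:
    """Filter to content tokens, assigning consecutive content positions."""
    out = []
    for t in annotated:
        if t.is_content:
            out.append(replace(t, position_content=len(out)))
    return out


_SURFACE_RE = re.compile(r"[A-Za-z0-9]+(?:[-'’][A-Za-z0-9]+)*")


def surface_tokens(text: str) -> list[str]:
    """Original-case tokens parallel to :func:`tokenize` output."""
    return _SURFACE_RE.findall(text)


def preprocess_text(text: str, backend: str = "rulebased") -> list[AnnotatedToken]:
    """Tokenize, annotate, and filter a raw text to its content stream."""
    surfaces = surface_tokens(text)
    lowered = [s.lower() for s in surfaces]
    return content_stream(annotate(lowered, surfaces, backend=backend))
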