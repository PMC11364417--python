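"""Shared fixtures: illustrative news snippets and small synthetic corpora."""

import pytest

from collotopics.synthetic_data import GeneratorSpec, generate

# Illustrative news-style snippets (violence / complications / contraception
# narratives around a pregnancy keyword) used to pin down the content filter
# and the ±6 collocation window.
SAMPLE_TEXT_VIOLENCE = (
    "…told The New York Times that 16 women and children, including two "
    "pregnant women, were killed in the revenge attack…"
)
SAMPLE_TEXT_COMPLICATIONS = (
    "…followed by eclampsia, a condition in which one or more convulsions "
    "occur in a pregnant woman suffering from hypertension, and "
    "abortion-related complications…"
)
SAMPLE_TEXT_CONTRACEPTION = (
    "…others use abortion pills to bring pregnancy to an end; these women "
    "are criminalised—they risk arrest and prosecution…"
)

#: Collocational candidates each snippet illustrates for its theme.
SAMPLE_CANDIDATES = {
    SAMPLE_TEXT_VIOLENCE: ["killed", "revenge", "attack"],
    SAMPLE_TEXT_COMPLICATIONS: [
        "eclampsia", "condition", "convulsions", "suffering", "hypertension",
        "complications", "abortion-related",
    ],
    SAMPLE_TEXT_CONTRACEPTION: [
        "abortion", "pills", "end", "criminalised", "risk", "arrest", "prosecution",
    ],
}


@pytest.fixture(scope="session")
def small_corpus():
    """A small 5-region synthetic corpus with its ground truth (fixed seed)."""
    spec = GeneratorSpec(docs_per_region=40, doc_length_mean=120, seed=7)
    docs, truth = generate(spec)
    return spec, docs, truth
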