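import random

import pytest

from gpcranno.kb import build_dictionaries, species_dictionary
from gpcranno.matching import ScoringParams
from gpcranno.ner import (
    find_protein_mentions,
    find_species_mentions,
    normalize_protein,
)
from gpcranno.segmentation import segment, token_distance


def _mentions(text, kb, scoring=None):
    dicts = build_dictionaries(kb, scoring=scoring)
    _, tokens = segment(text)
    return find_protein_mentions(text, dicts, tokens), tokens


def _annotate_proteins(text, kb):
    mentions, tokens = _mentions(text, kb)
    species = find_species_mentions(text, species_dictionary(kb))
    return [normalize_protein(m, species, tokens, kb) for m in mentions], species


def test_shared_description_stays_unresolved_without_species(rhodopsin_kb):
    mentions, _ = _annotate_proteins("Rhodopsin is a photoreceptor.", rhodopsin_kb)
    (m,) = mentions
    assert {name for name, _ in m.candidates} == {"OPSD_HUMAN", "OPSD_BOVIN"}
    assert m.normalized is None


def test_species_context_resolves_shared_description(rhodopsin_kb):
    mentions, _ = _annotate_proteins(
        "We purified human rhodopsin from retina.", rhodopsin_kb
    )
    (m,) = mentions
    assert m.normalized == "OPSD_HUMAN"
    assert m.resolving_species == 9606


def test_normalized_taxid_always_matches_resolving_species(rhodopsin_kb):
    mentions, _ = _annotate_proteins(
        "Both human rhodopsin and bovine rhodopsin were compared; "
        "rhodopsin is conserved.", rhodopsin_kb
    )
    for m in mentions:
        if m.resolving_species is not None:
            assert rhodopsin_kb.proteins[m.normalized].taxid == m.resolving_species


def test_greek_latin_variants_match_at_full_score(h1_kb):
    h1_kb.proteins["HRH1_CAVPO"].descriptions.append("β2-adrenergic receptor")
    mentions, _ = _mentions(
        "the beta2-adrenergic receptor was cloned", h1_kb
    )
    (m,) = mentions
    assert m.span.text == "beta2-adrenergic receptor"
    assert m.best_score == 1.0


def test_single_edit_rejected_by_strict_identifier_class(h1_kb):
    mentions, _ = _mentions("the HRH2 gene", h1_kb)  # gene symbol is HRH1
    assert mentions == []


def test_tolerant_description_class_accepts_small_typo(h1_kb):
    mentions, _ = _mentions("the histamine H1 reeceptor was expressed", h1_kb)
    (m,) = mentions
    assert m.candidates[0][0] == "HRH1_CAVPO"
    assert 0.8 <= m.best_score < 1.0


def test_lowering_distance_threshold_never_adds_mentions(h1_kb):
    from gpcranno.kb import DictClass, DEFAULT_SCORING

    text = "the histamine H1 reeceptor was expressed in cells"
    counts = []
    for dist in (0.3, 0.2, 0.1, 0.0):
        scoring = dict(DEFAULT_SCORING)
        scoring[DictClass.DESCRIPTION] = ScoringParams(
            max_normalized_distance=dist, greek_latin=True
        )
        mentions, _ = _mentions(text, h1_kb, scoring=scoring)
        counts.append(len(mentions))
    assert counts == sorted(counts, reverse=True)


def test_species_mentions_found_and_word_bounded(rhodopsin_kb):
    matcher = species_dictionary(rhodopsin_kb)
    sms = find_species_mentions("human and bovine samples; Homo sapiens.", matcher)
    assert [(s.span.text, s.taxid) for s in sms] == [
        ("human", 9606), ("bovine", 9913), ("Homo sapiens", 9606),
    ]
    assert find_species_mentions("the humane society", matcher) == []
    assert find_species_mentions("", matcher) == []


def _oracle_resolve(mention, species_mentions, tokens, kb):
    """Exhaustive-pairing re-implementation of the documented rule chain."""
    best = mention.candidates[0][1]
    stratum = [n for n, s in mention.candidates if s >= best - 1e-9]
    if not species_mentions:
        return stratum[0] if len(stratum) == 1 else None
    attested = {sm.taxid for sm in species_mentions}
    filtered = [n for n in stratum if kb.proteins[n].taxid in attested]
    if not filtered:
        return None
    pairs = []
    for sm in species_mentions:
        if kb.proteins and sm.taxid in {kb.proteins[n].taxid for n in filtered}:
            d = token_distance(sm.span, mention.span, tokens, strict=False)
            preceding = 0 if sm.span.start < mention.span.start else 1
            pairs.append(((d, preceding, sm.span.start), sm.taxid))
    pairs.sort()
    winner = [n for n in filtered if kb.proteins[n].taxid == pairs[0][1]]
    return winner[0] if len(winner) == 1 else None


def test_equidistant_species_tie_prefers_preceding_and_matches_oracle(rhodopsin_kb):
    # "bovine" and "human" sit two tokens away on either side of the mention
    text = "Samples from bovine retina contained rhodopsin and also human material."
    mentions, species = _annotate_proteins(text, rhodopsin_kb)
    (m,) = mentions
    _, tokens = segment(text)
    assert m.normalized == "OPSD_BOVIN"  # nearest preceding wins the tie
    assert m.normalized == _oracle_resolve(m, species, tokens, rhodopsin_kb)


def test_randomized_documents_match_exhaustive_pairing_oracle(rhodopsin_kb):
    rng = random.Random(23)
    words = ["human", "bovine", "rhodopsin", "binds", "retinal", "the", "assay"]
    for _ in range(150):
        text = " ".join(rng.choice(words) for _ in range(rng.randint(3, 15))) + "."
        mentions, species = _annotate_proteins(text, rhodopsin_kb)
        _, tokens = segment(text)
        for m in mentions:
            assert m.normalized == _oracle_resolve(m, species, tokens, rhodopsin_kb)
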