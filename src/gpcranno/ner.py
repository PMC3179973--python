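"""Protein and species mention detection, and species-driven normalization.

Proteins are found by approximate dictionary matching over token windows;
each dictionary class scores with its own parameters (strict for gene and
protein identifiers, tolerant for free-text descriptions). A mention is
*normalized* — bound to a unique knowledge-base entry — only when its
candidates can be narrowed to one, using the species mentioned in the
document: "rhodopsin" alone stays unresolved when the knowledge base holds a
rhodopsin for more than one species, while "human rhodopsin" resolves via
the nearby species mention. Species context is document-wide; nearness (in
tokens) only breaks ties among attested species.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from .kb import DictClass, Dictionary, KnowledgeBase, SpeciesMatcher
from .matching import match_score
from .segmentation import Mention, Token, token_distance
from .segmentation import _TOKEN_RE  # shared tokenizer for key length stats

#: Windows may exceed the longest dictionary key by this many tokens and
#: still be scored approximately (insertions on either side).
_WINDOW_SLACK = 1
_MAX_WINDOW = 8

_CLASS_PRIORITY = {
    DictClass.PROTEIN_ID: 0,
    DictClass.GENE_ID: 1,
    DictClass.DESCRIPTION: 2,
}


@dataclass(frozen=True)
class ProteinMention:
    """A protein mention with its scored candidates.

    ``candidates`` holds ``(entry_name, score)`` pairs, best first;
    ``normalized`` is set only when resolution criteria are met, and is then
    always one of the candidates.
    """

    span: Mention
    dclass: DictClass
    candidates: tuple[tuple[str, float], ...]
    normalized: str | None = None
    resolving_species: int | None = None

    @property
    def best_score(self) -> float:
        return self.candidates[0][1] if self.candidates else 0.0


@dataclass(frozen=True)
class SpeciesMention:
    span: Mention
    taxid: int


def find_species_mentions(text: str, matcher: SpeciesMatcher) -> list[SpeciesMention]:
    """Every knowledge-base species name occurring in ``text`` (word-bounded)."""
    return [
        SpeciesMention(span=Mention(s, e, text[s:e]), taxid=taxid)
        for s, e, taxid in matcher.finditer(text)
    ]


def _key_token_count(key: str) -> int:
    return len(_TOKEN_RE.findall(key))


def find_protein_mentions(
    text: str,
    dictionaries: list[Dictionary],
    tokens: list[Token],
) -> list[ProteinMention]:
    """Scan token windows against every dictionary; resolve overlaps.

    Candidate spans are scored with the firing dictionary's parameters;
    windows below the class acceptance threshold are discarded. Overlapping
    mentions are resolved longest-span first, then highest score, so
    "histamine H1 receptor" beats an embedded "H1" gene-symbol hit.
    """
    raw: dict[tuple[int, int], list[tuple[DictClass, str, float]]] = {}
    for d in dictionaries:
        if not d.entries:
            continue
        exact_index: dict[str, list[str]] = {}
        for key in d.entries:
            exact_index.setdefault(d.scoring.canonicalize(key), []).append(key)
        max_n = min(
            _MAX_WINDOW,
            max(_key_token_count(k) for k in d.entries) + _WINDOW_SLACK,
        )
        approx = d.scoring.max_normalized_distance > 1e-9
        threshold = 1.0 - d.scoring.max_normalized_distance - 1e-9
        for i, tok in enumerate(tokens):
            if not tok.text[:1].isalnum():
                continue
            for j in range(i, min(i + max_n, len(tokens))):
                end_tok = tokens[j]
                if end_tok.sentence_index != tok.sentence_index:
                    break
                if not end_tok.text[-1:].isalnum():
                    continue
                surface = text[tok.start:end_tok.end]
                canon = d.scoring.canonicalize(surface)
                hits: dict[str, float] = {}
                for key in exact_index.get(canon, ()):
                    for entry in d.entries[key]:
                        hits[entry] = 1.0
                if approx and not hits:
                    for key, entries in d.entries.items():
                        score = match_score(surface, key, d.scoring)
                        if score >= threshold:
                            for entry in entries:
                                hits[entry] = max(hits.get(entry, 0.0), score)
                if hits:
                    cell = raw.setdefault((tok.start, end_tok.end), [])
                    for entry, score in hits.items():
                        cell.append((d.dclass, entry, score))

    mentions: list[ProteinMention] = []
    for (start, end), cands in raw.items():
        best = max(score for _, _, score in cands)
        dclass = min(
            (dc for dc, _, sc in cands if sc >= best - 1e-9),
            key=lambda dc: _CLASS_PRIORITY[dc],
        )
        per_entry: dict[str, float] = {}
        for _, entry, score in cands:
            per_entry[entry] = max(per_entry.get(entry, 0.0), score)
        ordered = tuple(
            sorted(per_entry.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        mentions.append(ProteinMention(
            span=Mention(start, end, text[start:end]),
            dclass=dclass,
            candidates=ordered,
        ))

    # exact hits outrank any overlapping approximate hit (a fuzzy window that
    # swallows neighbouring words must not shadow the clean match inside it);
    # within a score tier, longest span wins, then highest score
    mentions.sort(key=lambda m: (
        0 if m.best_score >= 1.0 - 1e-9 else 1,
        -len(m.span), -m.best_score, m.span.start,
    ))
    kept: list[ProteinMention] = []
    for m in mentions:
        if not any(m.span.overlaps(k.span) for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.span.start)
    return kept


def _nearest_species(
    target: Mention,
    species_mentions: list[SpeciesMention],
    tokens: list[Token],
) -> SpeciesMention:
    """Nearest species mention by token distance.

    Ties prefer the nearest *preceding* mention, then the earlier one in the
    document.
    """
    def rank(sm: SpeciesMention) -> tuple[int, int, int]:
        dist = token_distance(sm.span, target, tokens, strict=False)
        preceding = 0 if sm.span.start < target.start else 1
        return (dist, preceding, sm.span.start)

    return min(species_mentions, key=rank)


def normalize_protein(
    mention: ProteinMention,
    species_mentions: list[SpeciesMention],
    tokens: list[Token],
    kb: KnowledgeBase,
) -> ProteinMention:
    """Resolve a mention to a unique entry using document species context.

    Only candidates tied at the best match score compete. When the document
    mentions any species, candidates are filtered to attested species and the
    species mention nearest to the protein mention picks the winner; a
    mention whose candidates cannot be narrowed to exactly one stays
    unresolved (its candidate list is kept so downstream consumers can report
    the ambiguity).
    """
    if not mention.candidates:
        return mention
    best = mention.best_score
    stratum = [name for name, score in mention.candidates if score >= best - 1e-9]

    if not species_mentions:
        if len(stratum) == 1:
            return replace(mention, normalized=stratum[0])
        return mention

    attested = {sm.taxid for sm in species_mentions}
    filtered = [n for n in stratum if kb.proteins[n].taxid in attested]
    if not filtered:
        # the document's species evidence contradicts every candidate; keep
        # the pre-filter list and stay unresolved rather than guessing
        return mention

    relevant_taxids = {kb.proteins[n].taxid for n in filtered}
    relevant = [sm for sm in species_mentions if sm.taxid in relevant_taxids]
    chosen = _nearest_species(mention.span, relevant, tokens)
    final = [n for n in filtered if kb.proteins[n].taxid == chosen.taxid]
    if len(final) == 1:
        return replace(
            mention, normalized=final[0], resolving_species=chosen.taxid
        )
    return mention
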