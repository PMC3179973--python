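"""Grounding residue/mutation records on normalized proteins.

A record is grounded by ranking the document's normalized protein mentions —
same sentence first, then ascending token distance, then nearest-preceding,
then document order — and taking the highest-ranked protein whose reference
sequence *validates* the record. Validation succeeds directly (the stated
wild-type residue matches the sequence at the stated position), via an
article-wide numbering offset (articles often number residues relative to a
construct with a signal peptide or a different isoform), or via generic
residue-number lookup (Ballesteros-Weinstein / Oliveira labels are mapped to
sequential positions through the knowledge base's numbering tables). When no
candidate validates, the top-ranked candidate is kept with
``validation="unvalidated"`` so recall can be audited.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

from .grammar import MutationRecord, ResidueRecord
from .kb import KnowledgeBase, ProteinEntry
from .ner import ProteinMention
from .numbering import GeneralNumber, Scheme
from .segmentation import Mention, Sentence, Token, sentence_of, token_distance

#: Half-width of the offset search window. ±200 covers cleaved signal
#: peptides and isoform N-terminal differences seen in GPCR constructs.
DEFAULT_OFFSET_WINDOW = 200


class Validation(str, enum.Enum):
    VALIDATED = "validated"
    CORRECTED_BY_OFFSET = "corrected_by_offset"
    GENERAL_NUMBER_LOOKUP = "general_number_lookup"
    UNVALIDATED = "unvalidated"


@dataclass(frozen=True)
class OffsetSolution:
    """An inferred article-vs-knowledge-base numbering offset.

    ``offset`` = article position − knowledge-base position (positive when
    the article counts extra N-terminal residues, e.g. a signal peptide).
    """

    offset: int
    n_consistent: int
    candidates_considered: tuple[int, ...]


@dataclass(frozen=True)
class GroundedAnnotation:
    """A residue/mutation record bound to one protein and sequence position.

    ``sequential_position`` is in knowledge-base sequence coordinates (1-based);
    ``applied_offset`` is the article-minus-KB correction that was applied
    (0 when none). ``protein`` is empty when the record could not be grounded.
    """

    record: MutationRecord | ResidueRecord
    protein: str
    sequential_position: int | None
    applied_offset: int
    validation: Validation
    bw_label: str | None = None
    oliveira_label: str | None = None
    grounding_distance: int | None = None
    same_sentence: bool | None = None


# --------------------------------------------------------------------------
# Numbering-scheme conversion
# --------------------------------------------------------------------------

def general_to_sequential(entry: ProteinEntry, g: GeneralNumber) -> int | None:
    """Sequential position carrying generic number ``g``, or None if unmapped."""
    for pos, labels in entry.numbering.items():
        mapped = labels.bw if g.scheme is Scheme.BALLESTEROS_WEINSTEIN else labels.oliveira
        if mapped is not None and mapped.label == g.label:
            return pos
    return None


def sequential_to_general(
    entry: ProteinEntry, pos: int
) -> tuple[str | None, str | None]:
    """(BW label, Oliveira label) for a position; None where unmapped.

    Loop positions outside the structurally conserved regions have no generic
    number in either scheme.
    """
    if not 1 <= pos <= len(entry.sequence):
        raise IndexError(
            f"{entry.entry_name}: position {pos} outside 1..{len(entry.sequence)}"
        )
    labels = entry.numbering.get(pos)
    if labels is None:
        return None, None
    return (
        labels.bw.label if labels.bw else None,
        labels.oliveira.label if labels.oliveira else None,
    )


# --------------------------------------------------------------------------
# Offset resolution
# --------------------------------------------------------------------------

def _wild_type_of(record: MutationRecord | ResidueRecord) -> str | None:
    if isinstance(record, MutationRecord):
        return record.wild_type
    return record.amino_acid


def _consistent_at(entry: ProteinEntry, records, delta: int) -> int:
    n = 0
    for rec in records:
        aa = _wild_type_of(rec)
        if aa is None:
            continue
        pos = rec.position - delta
        if 1 <= pos <= len(entry.sequence) and entry.residue_at(pos) == aa:
            n += 1
    return n


def resolve_offset(
    entry: ProteinEntry,
    records: list[MutationRecord | ResidueRecord],
    window: int = DEFAULT_OFFSET_WINDOW,
) -> OffsetSolution | None:
    """Infer one numbering offset explaining a protein's sequential records.

    Scans every offset δ in [−window, +window], counting the records whose
    stated wild-type residue matches ``sequence[position − δ]``. Among the
    offsets explaining the most records, the smallest |δ| wins; an exact tie
    prefers positive δ (article numbering ahead of the database, the cleaved
    signal-peptide / longer-isoform case). Returns None when no offset
    explains any record.
    """
    seq_records = [
        r for r in records
        if r.scheme is Scheme.SEQUENTIAL and _wild_type_of(r) is not None
    ]
    if not seq_records:
        return None
    best_n = 0
    counts: dict[int, int] = {}
    for delta in range(-window, window + 1):
        n = _consistent_at(entry, seq_records, delta)
        if n > 0:
            counts[delta] = n
            best_n = max(best_n, n)
    if best_n == 0:
        return None
    candidates = sorted(
        (d for d, n in counts.items() if n == best_n),
        key=lambda d: (abs(d), -d),  # minimal |δ|, tie -> positive
    )
    return OffsetSolution(
        offset=candidates[0],
        n_consistent=best_n,
        candidates_considered=tuple(candidates),
    )


# --------------------------------------------------------------------------
# Grounding
# --------------------------------------------------------------------------

def rank_candidates(
    span: Mention,
    protein_mentions: list[ProteinMention],
    tokens: list[Token],
    sentences: list[Sentence],
) -> list[tuple[str, ProteinMention, tuple[int, int, int, int]]]:
    """Normalized protein mentions ranked for a record span.

    Rank key: same sentence first, then ascending token distance, then
    nearest-preceding, then document order. One (best) mention per protein.
    """
    rec_sentence = sentence_of(span, sentences)
    ranked: dict[str, tuple[tuple[int, int, int, int], ProteinMention]] = {}
    for pm in protein_mentions:
        if pm.normalized is None:
            continue
        dist = token_distance(pm.span, span, tokens, strict=False)
        same = sentence_of(pm.span, sentences) == rec_sentence
        key = (
            0 if same else 1,
            dist,
            0 if pm.span.start < span.start else 1,
            pm.span.start,
        )
        prev = ranked.get(pm.normalized)
        if prev is None or key < prev[0]:
            ranked[pm.normalized] = (key, pm)
    out = [(name, pm, key) for name, (key, pm) in ranked.items()]
    out.sort(key=lambda t: t[2])
    return out


def _try_validate(
    entry: ProteinEntry,
    record: MutationRecord | ResidueRecord,
    offset: int | None,
) -> tuple[int, int, Validation] | None:
    """(sequential_position, applied_offset, status) or None if invalid."""
    aa = _wild_type_of(record)
    if record.scheme is Scheme.SEQUENTIAL:
        pos = record.position
        if aa is not None:
            # a document-wide offset, once established for this protein, is
            # the article's numbering scheme: apply it before trusting a
            # coincidental direct hit at the uncorrected position
            if offset is not None and offset != 0:
                corrected = pos - offset
                if (
                    1 <= corrected <= len(entry.sequence)
                    and entry.residue_at(corrected) == aa
                ):
                    return corrected, offset, Validation.CORRECTED_BY_OFFSET
            if 1 <= pos <= len(entry.sequence) and entry.residue_at(pos) == aa:
                return pos, 0, Validation.VALIDATED
            return None
        # bare number: nothing to check against the sequence
        if offset is not None and offset != 0:
            corrected = pos - offset
            if 1 <= corrected <= len(entry.sequence):
                return corrected, offset, Validation.CORRECTED_BY_OFFSET
            return None
        return None
    # generic residue number: map through the numbering table
    assert record.general is not None
    pos = general_to_sequential(entry, record.general)
    if pos is None:
        return None
    if aa is not None and entry.residue_at(pos) != aa:
        return None
    return pos, 0, Validation.GENERAL_NUMBER_LOOKUP


def ground_record(
    record: MutationRecord | ResidueRecord,
    protein_mentions: list[ProteinMention],
    tokens: list[Token],
    sentences: list[Sentence],
    kb: KnowledgeBase,
    offsets: dict[str, OffsetSolution] | None = None,
) -> GroundedAnnotation:
    """Ground one record against the document's normalized protein mentions.

    ``offsets`` carries per-protein numbering offsets already inferred for
    this document (see :func:`resolve_offset`); grounding never invents an
    offset for a single record on its own.
    """
    offsets = offsets or {}
    ranked = rank_candidates(record.span, protein_mentions, tokens, sentences)
    if not ranked:
        return GroundedAnnotation(
            record=record, protein="", sequential_position=None,
            applied_offset=0, validation=Validation.UNVALIDATED,
        )
    for name, pm, key in ranked:
        entry = kb.proteins[name]
        sol = offsets.get(name)
        result = _try_validate(entry, record, sol.offset if sol else None)
        if result is not None:
            pos, applied, status = result
            bw, ol = sequential_to_general(entry, pos)
            return GroundedAnnotation(
                record=record, protein=name, sequential_position=pos,
                applied_offset=applied, validation=status,
                bw_label=bw, oliveira_label=ol,
                grounding_distance=key[1], same_sentence=key[0] == 0,
            )
    name, pm, key = ranked[0]
    entry = kb.proteins[name]
    pos = record.position if record.scheme is Scheme.SEQUENTIAL else None
    in_bounds = pos is not None and 1 <= pos <= len(entry.sequence)
    return GroundedAnnotation(
        record=record, protein=name,
        sequential_position=pos if in_bounds else None,
        applied_offset=0, validation=Validation.UNVALIDATED,
        grounding_distance=key[1], same_sentence=key[0] == 0,
    )


def ground_all(
    records: list[MutationRecord | ResidueRecord],
    protein_mentions: list[ProteinMention],
    tokens: list[Token],
    sentences: list[Sentence],
    kb: KnowledgeBase,
    window: int = DEFAULT_OFFSET_WINDOW,
) -> list[GroundedAnnotation]:
    """Ground every record, inferring one offset per (document, protein).

    Two passes: records are first attributed to their top-ranked protein to
    pool that protein's sequential records for offset inference (only when
    direct validation fails for at least one of them); the final pass grounds
    each record with the inferred offsets available.
    """
    attributed: dict[str, list[MutationRecord | ResidueRecord]] = {}
    needs_offset: set[str] = set()
    for rec in records:
        ranked = rank_candidates(rec.span, protein_mentions, tokens, sentences)
        if not ranked:
            continue
        name = ranked[0][0]
        attributed.setdefault(name, []).append(rec)
        if (
            rec.scheme is Scheme.SEQUENTIAL
            and _wild_type_of(rec) is not None
            and _try_validate(kb.proteins[name], rec, None) is None
        ):
            needs_offset.add(name)

    offsets: dict[str, OffsetSolution] = {}
    for name in sorted(needs_offset):
        sol = resolve_offset(kb.proteins[name], attributed[name], window=window)
        if sol is not None:
            offsets[name] = sol

    return [
        ground_record(rec, protein_mentions, tokens, sentences, kb, offsets)
        for rec in records
    ]
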