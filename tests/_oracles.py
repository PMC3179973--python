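"""Independent brute-force re-implementations of the grounding rule chain.

These oracles re-derive grounding decisions from the documented rules by
exhaustive enumeration — every (record, protein-mention) pair is scored, and
offsets are found by scanning the whole window — without calling into
:mod:`gpcranno.grounding`'s ranking/validation code paths.
"""
from __future__ import annotations

from gpcranno.numbering import Scheme
from gpcranno.segmentation import sentence_of, token_distance


def _wt(record):
    return getattr(record, "wild_type", None) or getattr(record, "amino_acid", None)


def oracle_rank(span, protein_mentions, tokens, sentences):
    """All (rank-key, entry) pairs, best first, one entry each."""
    rec_sent = sentence_of(span, sentences)
    pairs = []
    for pm in protein_mentions:
        if pm.normalized is None:
            continue
        key = (
            0 if sentence_of(pm.span, sentences) == rec_sent else 1,
            token_distance(pm.span, span, tokens, strict=False),
            0 if pm.span.start < span.start else 1,
            pm.span.start,
        )
        pairs.append((key, pm.normalized))
    pairs.sort()
    seen, out = set(), []
    for key, name in pairs:
        if name not in seen:
            seen.add(name)
            out.append((key, name))
    return out


def oracle_offset(entry, records, window):
    counts = {}
    for delta in range(-window, window + 1):
        n = 0
        for r in records:
            aa = _wt(r)
            if aa is None or r.scheme is not Scheme.SEQUENTIAL:
                continue
            p = r.position - delta
            if 1 <= p <= len(entry.sequence) and entry.sequence[p - 1] == aa:
                n += 1
        if n:
            counts[delta] = n
    if not counts:
        return None
    best = max(counts.values())
    cands = sorted((d for d, n in counts.items() if n == best),
                   key=lambda d: (abs(d), -d))
    return cands[0]


def _oracle_validate(entry, record, offset):
    aa = _wt(record)
    L = len(entry.sequence)
    if record.scheme is Scheme.SEQUENTIAL:
        pos = record.position
        if aa is not None:
            if offset is not None and offset != 0:
                c = pos - offset
                if 1 <= c <= L and entry.sequence[c - 1] == aa:
                    return c, offset, "corrected_by_offset"
            if 1 <= pos <= L and entry.sequence[pos - 1] == aa:
                return pos, 0, "validated"
            return None
        if offset is not None and offset != 0 and 1 <= pos - offset <= L:
            return pos - offset, offset, "corrected_by_offset"
        return None
    # generic number: scan the numbering table
    for pos, labels in entry.numbering.items():
        g = labels.bw if record.scheme is Scheme.BALLESTEROS_WEINSTEIN else labels.oliveira
        if g is not None and g.label == record.general.label:
            if aa is not None and entry.sequence[pos - 1] != aa:
                return None
            return pos, 0, "general_number_lookup"
    return None


def oracle_ground_all(records, protein_mentions, tokens, sentences, kb, window=200):
    """(protein, sequential_position, applied_offset, validation) per record."""
    attributed, needs = {}, set()
    for r in records:
        ranked = oracle_rank(r.span, protein_mentions, tokens, sentences)
        if not ranked:
            continue
        top = ranked[0][1]
        attributed.setdefault(top, []).append(r)
        aa = _wt(r)
        if r.scheme is Scheme.SEQUENTIAL and aa is not None:
            entry = kb.proteins[top]
            L = len(entry.sequence)
            if not (1 <= r.position <= L and entry.sequence[r.position - 1] == aa):
                needs.add(top)
    offsets = {}
    for name in needs:
        o = oracle_offset(kb.proteins[name], attributed[name], window)
        if o is not None:
            offsets[name] = o

    out = []
    for r in records:
        ranked = oracle_rank(r.span, protein_mentions, tokens, sentences)
        if not ranked:
            out.append(("", None, 0, "unvalidated"))
            continue
        chosen = None
        for key, name in ranked:
            v = _oracle_validate(kb.proteins[name], r, offsets.get(name))
            if v is not None:
                chosen = (name, *v)
                break
        if chosen is None:
            name = ranked[0][1]
            L = len(kb.proteins[name].sequence)
            pos = r.position if (
                r.scheme is Scheme.SEQUENTIAL and 1 <= r.position <= L
            ) else None
            chosen = (name, pos, 0, "unvalidated")
        out.append(chosen)
    return out
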