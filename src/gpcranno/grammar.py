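"""Regex grammar for point-mutation and residue mentions.

Point mutations appear in the literature in many surface forms around the
``XnY`` theme (wild-type residue X, sequence position n, substituted residue
Y): compact one- or three-letter forms ("D98F", "Asp98Phe"), arrow forms
("Asp98 → Phe"), hyphen forms with a repeated position ("Asp98-Phe98"),
"to"-forms ("D98 to phenylalanine") and fully verbal forms ("Asp 98 was
mutated to phenylalanine"). All supported forms parse to the same canonical
(wild-type, position, mutant) triple in one-letter codes. Residue mentions
cover "Trp161" / "Trp 161" / "W161", bare Ballesteros-Weinstein labels such
as "3.50" (cue-guarded so decimal measurements do not fire), and cue-driven
Oliveira/GPCRDB integer labels.

The grammar deliberately trades a little recall for precision on distractor
patterns common in articles: single-letter compact mutations need a two-digit
position (so "H1R"-style receptor synonyms and "T4 lysozyme" never parse),
and bare generic-number labels need a nearby cue word like "residue".
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .numbering import BWLabelError, GeneralNumber, Scheme, parse_bw_label
from .segmentation import Mention, Sentence

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Amino-acid vocabulary
# --------------------------------------------------------------------------

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

FULL_TO_1 = {
    "alanine": "A", "arginine": "R", "asparagine": "N",
    "aspartic acid": "D", "aspartate": "D", "cysteine": "C",
    "glutamine": "Q", "glutamic acid": "E", "glutamate": "E",
    "glycine": "G", "histidine": "H", "isoleucine": "I", "leucine": "L",
    "lysine": "K", "methionine": "M", "phenylalanine": "F", "proline": "P",
    "serine": "S", "threonine": "T", "tryptophan": "W", "tyrosine": "Y",
    "valine": "V",
}

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA1_TO_FULL = {v: k for k, v in FULL_TO_1.items() if k not in ("aspartate", "glutamate")}


def normalize_amino_acid(token: str) -> str:
    """Canonical one-letter code for a 1-letter, 3-letter or full-name token.

    >>> normalize_amino_acid("Asp"), normalize_amino_acid("phenylalanine")
    ('D', 'F')
    """
    t = " ".join(token.split())
    if len(t) == 1 and t.upper() in AA1:
        return t.upper()
    if len(t) == 3 and t.capitalize() in AA3_TO_1:
        return AA3_TO_1[t.capitalize()]
    if t.lower() in FULL_TO_1:
        return FULL_TO_1[t.lower()]
    raise ValueError(f"unrecognized amino-acid token: {token!r}")


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRecord:
    """A parsed point-mutation mention, canonicalized to one-letter codes.

    ``position`` is the number as printed in the article (not yet mapped to
    knowledge-base coordinates); for the Ballesteros-Weinstein scheme the
    generic number is carried in ``general`` and ``position`` holds its
    intra-helix index.
    """

    wild_type: str
    position: int
    mutant: str
    scheme: Scheme
    span: Mention
    general: GeneralNumber | None = None
    silent: bool = False


@dataclass(frozen=True)
class ResidueRecord:
    """A parsed residue mention; ``amino_acid`` is None when unstated."""

    amino_acid: str | None
    position: int
    scheme: Scheme
    span: Mention
    general: GeneralNumber | None = None


# --------------------------------------------------------------------------
# Pattern assembly
# --------------------------------------------------------------------------

_AA3_ALT = "|".join(AA3_TO_1)
_FULL_ALT = "|".join(
    sorted((k.replace(" ", r"\s+") for k in FULL_TO_1), key=len, reverse=True)
)
_AA1_ALT = f"[{AA1}]"
# three-letter codes are accepted in any capitalization when glued to a
# position; full names likewise
_AA3I = f"(?i:{_AA3_ALT})"
_FULLI = f"(?i:{_FULL_ALT})"
_ARROW = r"(?:-->|->|→)"
_POS = r"(?:[1-8]\.\d{2}|\d+)"  # BW label or plain sequential number

_MUTATION_PATTERNS: list[tuple[str, re.Pattern[str]]] = [
    # D98F / Asp98Phe / D3.50N — no internal spaces; single-letter pairs are
    # handled by the dedicated pattern below with a 2-digit position guard
    ("compact3", re.compile(
        rf"\b(?P<wt>{_AA3I})(?P<pos>{_POS})(?P<mut>{_AA3I}|{_AA1_ALT})(?![A-Za-z0-9]|\.\d)"
    )),
    ("compact1", re.compile(
        rf"\b(?P<wt>{_AA1_ALT})(?P<pos>[1-8]\.\d{{2}}|\d{{2,}})(?P<mut>{_AA1_ALT})(?![A-Za-z0-9]|\.\d)"
    )),
    ("compact13", re.compile(
        rf"\b(?P<wt>{_AA1_ALT})(?P<pos>{_POS})(?P<mut>{_AA3I})(?![A-Za-z0-9]|\.\d)"
    )),
    # Asp98 → Phe, D98->F
    ("arrow", re.compile(
        rf"\b(?P<wt>{_AA3I}|{_AA1_ALT})\s?(?P<pos>{_POS})\s*{_ARROW}\s*"
        rf"(?P<mut>{_FULLI}|{_AA3I}|{_AA1_ALT})(?![A-Za-z0-9]|\.\d)"
    )),
    # Asp98-Phe98 (positions must agree)
    ("hyphen", re.compile(
        rf"\b(?P<wt>{_AA3I}|{_AA1_ALT})(?P<pos>\d+)[-‐–](?P<mut>{_AA3I}|{_AA1_ALT})"
        rf"(?P<pos2>\d+)(?![A-Za-z0-9]|\.\d)"
    )),
    # D98 to phenylalanine / Asp 98 was mutated to phenylalanine
    ("verbal", re.compile(
        rf"\b(?P<wt>{_AA3I}|{_AA1_ALT})\s?(?P<pos>{_POS})\s+"
        rf"(?:(?:was|is|were|has\s+been)\s+)?"
        rf"(?:mutated\s+to|mutated\s+into|substituted\s+(?:with|by|to)|"
        rf"changed\s+(?:to|into)|replaced\s+(?:with|by)|exchanged\s+(?:for|with)|to)\s+"
        rf"(?:an?\s+)?(?P<mut>{_FULLI}|{_AA3I}|{_AA1_ALT})(?![A-Za-z0-9]|\.\d)"
    )),
]

_RESIDUE_PATTERNS: list[tuple[str, re.Pattern[str]]] = [
    # Trp243 / Trp 161 / tryptophan 161 / Trp3.50
    ("res3", re.compile(
        rf"\b(?P<aa>{_FULLI}|{_AA3I})\s?(?P<pos>{_POS})(?![A-Za-z0-9]|\.\d)"
    )),
    # W161 — two-digit minimum position, so "T4" (lysozyme) never fires
    ("res1", re.compile(
        rf"\b(?P<aa>{_AA1_ALT})(?P<pos>[1-8]\.\d{{2}}|\d{{2,}})(?![A-Za-z0-9]|\.\d)"
    )),
    # bare BW label; accepted only near a cue word (checked post-hoc)
    ("bw_bare", re.compile(r"\b(?P<pos>[1-8]\.\d{2})(?![A-Za-z0-9]|\.\d)")),
]

_OLIVEIRA_RE = re.compile(
    r"(?i:\b(?:oliveira|gpcrdb)\s+(?:number|numbering|position|residue)?\s*"
    r"(?P<pos>\d{3})\b)"
)

DEFAULT_BW_CUE_WORDS = frozenset(
    {"residue", "residues", "position", "positions", "site", "sites"}
)
DEFAULT_UNIT_BLOCKLIST = frozenset(
    {"nm", "mm", "um", "µm", "μm", "pm", "å", "a", "kda", "mg", "ml", "µl",
     "%", "fold", "hz", "kcal", "kj", "min", "h", "s"}
)


def _pos_and_scheme(raw: str) -> tuple[int, Scheme, GeneralNumber | None]:
    if "." in raw:
        g = parse_bw_label(raw)
        return g.index, Scheme.BALLESTEROS_WEINSTEIN, g
    return int(raw), Scheme.SEQUENTIAL, None


def _dedupe_longest(spans: list[tuple[Mention, object]]) -> list[object]:
    """Longest-span-wins overlap resolution, ties broken by earlier start."""
    order = sorted(spans, key=lambda sm: (-(len(sm[0])), sm[0].start))
    kept: list[tuple[Mention, object]] = []
    for span, rec in order:
        if not any(span.overlaps(k) for k, _ in kept):
            kept.append((span, rec))
    kept.sort(key=lambda sm: sm[0].start)
    return [rec for _, rec in kept]


def find_mutation_mentions(
    text: str, sentences: list[Sentence] | None = None
) -> list[MutationRecord]:
    """All point-mutation mentions in ``text``, canonicalized.

    Overlapping candidate matches are resolved longest-span-wins. Hyphen
    forms with disagreeing positions ("Asp98-Phe99") are rejected and logged.
    Silent substitutions (wild-type equals mutant) are emitted with
    ``silent=True``.
    """
    found: list[tuple[Mention, object]] = []
    for name, pat in _MUTATION_PATTERNS:
        for m in pat.finditer(text):
            if name == "hyphen" and m.group("pos") != m.group("pos2"):
                logger.warning(
                    "rejected inconsistent mutation pattern %r at %d",
                    m.group(), m.start(),
                )
                continue
            try:
                wt = normalize_amino_acid(m.group("wt"))
                mut = normalize_amino_acid(m.group("mut"))
                pos, scheme, general = _pos_and_scheme(m.group("pos"))
            except (ValueError, BWLabelError):  # pragma: no cover - defensive
                continue
            span = Mention(m.start(), m.end(), m.group())
            found.append((span, MutationRecord(
                wild_type=wt, position=pos, mutant=mut, scheme=scheme,
                span=span, general=general, silent=wt == mut,
            )))
    return _dedupe_longest(found)  # type: ignore[return-value]


def _bw_cue_ok(
    text: str, start: int, cue_words: frozenset[str], units: frozenset[str]
) -> bool:
    """Accept a bare BW label only in a residue context.

    Walk left over immediately preceding label/connective tokens looking for
    a cue word ("residues 3.50 and 6.48" accepts both); reject labels followed
    by a measurement unit ("3.50 nM").
    """
    after = re.match(r"\s*([A-Za-zÅµμ%]+)", text[start:])
    # ``start`` here is the match *end*; see caller
    if after and after.group(1).lower() in units:
        return False
    return True


def _preceded_by_cue(
    text: str, start: int, cue_words: frozenset[str]
) -> bool:
    left = text[:start]
    connective = re.compile(r"(?:[1-8]\.\d{2}|and|or|,|\s)+$")
    m = connective.search(left)
    if m:
        left = left[: m.start()]
    w = re.search(r"([A-Za-z]+)$", left)
    return bool(w and w.group(1).lower() in cue_words)


def find_residue_mentions(
    text: str,
    sentences: list[Sentence] | None = None,
    *,
    mutation_spans: list[Mention] | None = None,
    bw_cue_words: frozenset[str] = DEFAULT_BW_CUE_WORDS,
    unit_blocklist: frozenset[str] = DEFAULT_UNIT_BLOCKLIST,
    oliveira_enabled: bool = True,
) -> list[ResidueRecord]:
    """All residue mentions, suppressing sub-spans of accepted mutations."""
    found: list[tuple[Mention, object]] = []
    for name, pat in _RESIDUE_PATTERNS:
        for m in pat.finditer(text):
            raw_pos = m.group("pos")
            if name == "bw_bare":
                if not _preceded_by_cue(text, m.start(), bw_cue_words):
                    continue
                if not _bw_cue_ok(text, m.end(), bw_cue_words, unit_blocklist):
                    continue
                aa: str | None = None
            else:
                try:
                    aa = normalize_amino_acid(m.group("aa"))
                except ValueError:
                    continue
            try:
                pos, scheme, general = _pos_and_scheme(raw_pos)
            except BWLabelError:
                continue
            span = Mention(m.start(), m.end(), m.group())
            found.append((span, ResidueRecord(
                amino_acid=aa, position=pos, scheme=scheme, span=span,
                general=general,
            )))
    if oliveira_enabled:
        for m in _OLIVEIRA_RE.finditer(text):
            idx = int(m.group("pos"))
            span = Mention(m.start("pos"), m.end("pos"), m.group("pos"))
            found.append((span, ResidueRecord(
                amino_acid=None, position=idx, scheme=Scheme.OLIVEIRA,
                span=span,
                general=GeneralNumber(scheme=Scheme.OLIVEIRA, index=idx),
            )))
    records = _dedupe_longest(found)
    if mutation_spans:
        records = [
            r for r in records
            if not any(ms.contains(r.span) for ms in mutation_spans)
        ]
    return records  # type: ignore[return-value]
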