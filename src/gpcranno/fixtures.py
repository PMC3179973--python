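"""Seeded generator of knowledge bases and synthetic articles with gold spans.

The generator emulates the article/knowledge-base pairing the annotation
pipeline consumes: a small receptor knowledge base (synthetic sequences,
descriptions, gene symbols, generic-number tables) and article-like documents
that mention its proteins and species, plant point mutations in the supported
notation families (optionally with a numbering offset emulating a
signal-peptide or isoform mismatch), and interleave distractor sentences
(decimal measurements, figure references, fusion-partner and cell-line names)
to exercise precision. Every planted span is recorded as a gold annotation in
knowledge-base coordinates, so each pipeline stage can be scored without any
download. Generation is deterministic per seed.

Sequences are random with a rejection step forbidding short tandem repeats,
so offset recovery is well-posed (a planted offset is, with high probability,
the unique best explanation of the planted mutations). Gold grounding/status
fields assume each mutation sentence names its protein (the default
``same_sentence_fraction=1.0``); lower fractions are meant for oracle-based
tests that do not consult gold grounding.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, replace
from pathlib import Path

from .grammar import AA1, AA1_TO_3, AA1_TO_FULL
from .kb import (
    KnowledgeBase,
    PositionLabels,
    ProteinEntry,
    SpeciesEntry,
    save_kb,
)
from .numbering import GeneralNumber, Scheme, oliveira_number
from .pipeline import AnnotationSet

SPECIES_POOL: list[tuple[int, tuple[str, ...]]] = [
    (9606, ("human", "Homo sapiens")),
    (9913, ("bovine", "Bos taurus")),
    (10090, ("mouse", "murine", "Mus musculus")),
    (10116, ("rat", "Rattus norvegicus")),
    (10141, ("guinea pig", "Cavia porcellus")),
]

TAXID_SUFFIX = {9606: "HUMAN", 9913: "BOVIN", 10090: "MOUSE",
                10116: "RAT", 10141: "CAVPO"}

#: (entry code, description, gene symbol, curated synonyms)
FAMILY_POOL: list[tuple[str, str, str, tuple[str, ...]]] = [
    ("OPSD", "rhodopsin", "RHO", ()),
    ("HRH1", "histamine H1 receptor", "HRH1", ("H1R",)),
    ("AA3R", "adenosine A3 receptor", "ADORA3", ()),
    ("TRFR", "thyrotropin-releasing hormone receptor", "TRHR", ()),
    ("ADRB2", "β2-adrenergic receptor", "ADRB2", ("beta2-adrenergic receptor",)),
    ("ACM1", "muscarinic acetylcholine receptor M1", "CHRM1", ()),
]

NOTATION_FAMILIES = ("compact1", "compact3", "arrow", "hyphen", "to", "verbal")

DISTRACTORS = [
    "The dissociation constant was 3.50 nM.",
    "A fusion with T4 lysozyme improved crystallization.",
    "See Fig. 3B for details.",
    "Data are summarized on p. 98 of the supplement.",
    "Expression was carried out in HEK293 cells.",
    "The CHO-K1 cell line was used for binding assays.",
    "Binding decreased 2.5-fold upon agonist treatment.",
]


class GenerationError(ValueError):
    """The fixture specification is infeasible."""


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_proteins: int = 3
    n_species: int = 2
    sequence_length_range: tuple[int, int] = (300, 400)
    n_documents: int = 1
    proteins_per_document: int = 1
    n_mutation_mentions: int = 4
    n_residue_mentions: int = 1
    notation_mix: tuple[float, ...] = (1.0,) * len(NOTATION_FAMILIES)
    planted_offset: int = 0
    distractor_density: float = 0.3
    bw_coverage: float = 0.25
    same_sentence_fraction: float = 1.0

    def validate(self) -> None:
        if self.n_species < 1 or self.n_species > len(SPECIES_POOL):
            raise GenerationError(f"n_species must be 1..{len(SPECIES_POOL)}")
        if self.n_proteins < 1 or self.n_proteins > len(FAMILY_POOL) * self.n_species:
            raise GenerationError("n_proteins exceeds family x species pool")
        if len(self.notation_mix) != len(NOTATION_FAMILIES):
            raise GenerationError("notation_mix needs one weight per family")
        if sum(self.notation_mix) <= 0:
            raise GenerationError("notation_mix weights must sum > 0")
        if abs(self.planted_offset) > 200:
            raise GenerationError("planted_offset outside resolver window ±200")
        if not 0.0 <= self.bw_coverage <= 1.0:
            raise GenerationError("bw_coverage must be in [0, 1]")
        lo, hi = self.sequence_length_range
        if lo < 100 or hi < lo:
            raise GenerationError("sequence_length_range must be sane and >= 100")
        if max(25, 11 - self.planted_offset) >= lo - 10:
            raise GenerationError(
                "planted_offset leaves no admissible mutation positions"
            )
        per_helix = int(self.bw_coverage * hi) // 7 + 1
        if per_helix > 90:
            raise GenerationError("bw_coverage asks for more labels than a helix holds")


@dataclass(frozen=True)
class GoldAnnotation:
    """One expected annotation, in document and knowledge-base coordinates."""

    start: int
    end: int
    type: str  # species | protein | mutation | residue
    surface: str
    entry_name: str = ""
    taxid: int | None = None
    position: int | None = None
    status: str | None = None


@dataclass(frozen=True)
class FixtureDocument:
    doc_id: str
    text: str
    gold: tuple[GoldAnnotation, ...]


@dataclass(frozen=True)
class FixtureResult:
    kb: KnowledgeBase
    documents: tuple[FixtureDocument, ...]


# --------------------------------------------------------------------------
# Knowledge-base synthesis
# --------------------------------------------------------------------------

def _has_tandem_repeat(seq: str, kmin: int = 8, kmax: int = 10) -> bool:
    for k in range(kmin, kmax + 1):
        for i in range(len(seq) - 2 * k + 1):
            if seq[i:i + k] == seq[i + k:i + 2 * k]:
                return True
    return False


def _random_sequence(rng: random.Random, length: int) -> str:
    for _ in range(50):
        seq = "".join(rng.choice(AA1) for _ in range(length))
        if not _has_tandem_repeat(seq):
            return seq
    raise GenerationError("could not draw a repeat-free sequence")  # pragma: no cover


def _make_numbering(
    rng: random.Random, length: int, coverage: float
) -> dict[int, PositionLabels]:
    """Label ~coverage of positions across 7 synthetic helix segments."""
    total = int(coverage * length)
    per_helix = max(0, total // 7)
    numbering: dict[int, PositionLabels] = {}
    oliveira = 100
    for helix in range(1, 8):
        center = int(length * (helix - 0.5) / 7.5) + 1
        start_pos = center - per_helix // 2
        for j in range(per_helix):
            pos = start_pos + j
            index = 50 - per_helix // 2 + j
            if not (1 <= pos <= length and 0 <= index <= 99):
                continue
            bw = GeneralNumber(
                scheme=Scheme.BALLESTEROS_WEINSTEIN, helix=helix, index=index
            )
            numbering[pos] = PositionLabels(bw=bw, oliveira=oliveira_number(oliveira))
            oliveira += 1
    return numbering


def make_kb(spec: FixtureSpec, rng: random.Random | None = None) -> KnowledgeBase:
    spec.validate()
    rng = rng or random.Random(spec.seed)
    species_list = SPECIES_POOL[: spec.n_species]
    species = {taxid: SpeciesEntry(taxid=taxid, names=names)
               for taxid, names in species_list}
    proteins: dict[str, ProteinEntry] = {}
    lo, hi = spec.sequence_length_range
    for i in range(spec.n_proteins):
        code, desc, gene, synonyms = FAMILY_POOL[i // spec.n_species]
        taxid, _ = species_list[i % spec.n_species]
        entry_name = f"{code}_{TAXID_SUFFIX[taxid]}"
        length = rng.randint(lo, hi)
        proteins[entry_name] = ProteinEntry(
            entry_name=entry_name,
            accession=f"P{rng.randint(0, 99999):05d}",
            taxid=taxid,
            gene_symbols=[gene],
            descriptions=[desc],
            synonyms=list(synonyms),
            sequence=_random_sequence(rng, length),
            numbering=_make_numbering(rng, length, spec.bw_coverage),
        )
    kb = KnowledgeBase(proteins=proteins, species=species)
    kb.validate()
    return kb


# --------------------------------------------------------------------------
# Document synthesis
# --------------------------------------------------------------------------

class _DocBuilder:
    """Accumulates sentences while tracking exact spans of planted items."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.offset = 0
        self.gold: list[GoldAnnotation] = []

    def add_sentence(self, pieces: list[tuple[str, GoldAnnotation | None]]) -> None:
        if self.parts:
            self.parts.append(" ")
            self.offset += 1
        for text, gold in pieces:
            if gold is not None:
                self.gold.append(replace(
                    gold, start=self.offset, end=self.offset + len(text),
                    surface=text,
                ))
            self.parts.append(text)
            self.offset += len(text)

    def text(self) -> str:
        return "".join(self.parts)


def _protein_phrase(
    entry: ProteinEntry, kb: KnowledgeBase
) -> list[tuple[str, GoldAnnotation | None]]:
    species_name = kb.species[entry.taxid].names[0]
    return [
        (species_name, GoldAnnotation(0, 0, "species", "", taxid=entry.taxid)),
        (" ", None),
        (entry.descriptions[0], GoldAnnotation(
            0, 0, "protein", "", entry_name=entry.entry_name, taxid=entry.taxid
        )),
    ]


def _render_mutation(family: str, wt: str, art: int, mut: str) -> str:
    if family == "compact1":
        return f"{wt}{art}{mut}"
    if family == "compact3":
        return f"{AA1_TO_3[wt]}{art}{AA1_TO_3[mut]}"
    if family == "arrow":
        return f"{AA1_TO_3[wt]}{art} → {AA1_TO_3[mut]}"
    if family == "hyphen":
        return f"{AA1_TO_3[wt]}{art}-{AA1_TO_3[mut]}{art}"
    if family == "to":
        return f"{wt}{art} to {AA1_TO_FULL[mut]}"
    if family == "verbal":
        return f"{AA1_TO_3[wt]} {art} was mutated to {AA1_TO_FULL[mut]}"
    raise GenerationError(f"unknown notation family {family!r}")


def _mutation_positions(
    rng: random.Random, entry: ProteinEntry, spec: FixtureSpec, n: int
) -> list[int]:
    lo = max(25, 11 - spec.planted_offset)
    hi = len(entry.sequence) - 10
    pool = list(range(lo, hi + 1))
    rng.shuffle(pool)
    return pool[:n]


def _build_document(
    rng: random.Random,
    kb: KnowledgeBase,
    spec: FixtureSpec,
    doc_id: str,
    entries: list[ProteinEntry],
) -> FixtureDocument:
    b = _DocBuilder()
    status = "validated" if spec.planted_offset == 0 else "corrected_by_offset"

    for entry in entries:
        b.add_sentence([
            ("We studied the ", None),
            *_protein_phrase(entry, kb),
            (" in detail", None),
            (".", None),
        ])
        if rng.random() < spec.distractor_density:
            b.add_sentence([(rng.choice(DISTRACTORS), None)])

    mut_positions = {
        entry.entry_name: _mutation_positions(
            rng, entry, spec, spec.n_mutation_mentions
        )
        for entry in entries
    }
    # each featured protein carries n_mutation_mentions of its own, so a
    # per-protein offset stays identifiable in multi-protein documents
    for i in range(spec.n_mutation_mentions * len(entries)):
        entry = entries[i % len(entries)]
        positions = mut_positions[entry.entry_name]
        if i // len(entries) >= len(positions):  # pragma: no cover - tiny seq
            break
        pos = positions[i // len(entries)]
        wt = entry.residue_at(pos)
        mut = rng.choice([a for a in AA1 if a != wt])
        art = pos + spec.planted_offset
        family = rng.choices(NOTATION_FAMILIES, weights=spec.notation_mix)[0]
        if family == "compact1" and art < 10:
            family = "compact3"
        token = _render_mutation(family, wt, art, mut)
        gold = GoldAnnotation(
            0, 0, "mutation", "", entry_name=entry.entry_name,
            position=pos, status=status,
        )
        named = rng.random() < spec.same_sentence_fraction
        if family == "verbal":
            if named:
                b.add_sentence([
                    ("In the ", None), *_protein_phrase(entry, kb),
                    (", ", None), (token, gold), (".", None),
                ])
            else:
                b.add_sentence([(token, gold), (".", None)])
        elif named:
            b.add_sentence([
                ("In the ", None), *_protein_phrase(entry, kb),
                (", the ", None), (token, gold),
                (" mutant showed reduced ligand binding", None), (".", None),
            ])
        else:
            b.add_sentence([
                ("The ", None), (token, gold),
                (" mutant showed reduced ligand binding", None), (".", None),
            ])
        if rng.random() < spec.distractor_density:
            b.add_sentence([(rng.choice(DISTRACTORS), None)])

    for i in range(spec.n_residue_mentions):
        entry = entries[i % len(entries)]
        labeled = sorted(p for p in entry.numbering if entry.numbering[p].bw)
        if i % 2 == 0 and labeled:
            pos = labeled[rng.randrange(len(labeled))]
            label = entry.numbering[pos].bw.label
            gold = GoldAnnotation(
                0, 0, "residue", "", entry_name=entry.entry_name,
                position=pos, status="general_number_lookup",
            )
            b.add_sentence([
                ("Residue ", None), (label, gold),
                (" is highly conserved in the ", None),
                *_protein_phrase(entry, kb), (".", None),
            ])
        else:
            # sequential residue with stated amino acid, e.g. "Trp161"
            positions = _mutation_positions(rng, entry, spec, 1)
            if not positions:  # pragma: no cover
                continue
            pos = positions[0]
            art = pos + spec.planted_offset
            token = f"{AA1_TO_3[entry.residue_at(pos)]}{art}"
            gold = GoldAnnotation(
                0, 0, "residue", "", entry_name=entry.entry_name,
                position=pos, status=status,
            )
            b.add_sentence([
                ("In the ", None), *_protein_phrase(entry, kb),
                (", residue ", None), (token, gold),
                (" lies near the binding pocket", None), (".", None),
            ])

    return FixtureDocument(doc_id=doc_id, text=b.text(), gold=tuple(b.gold))


def generate(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> FixtureResult:
    """Generate a knowledge base plus documents with gold annotations.

    With ``out_dir`` set, writes the knowledge-base files under
    ``out_dir/kb/``, one ``<doc_id>.txt`` per document under
    ``out_dir/docs/``, and a ``gold.tsv``. Deterministic per seed: the same
    spec yields byte-identical output.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    kb = make_kb(spec, rng)
    entries = list(kb.proteins.values())
    docs: list[FixtureDocument] = []
    for d in range(spec.n_documents):
        k = min(spec.proteins_per_document, len(entries))
        chosen = rng.sample(entries, k)
        docs.append(_build_document(rng, kb, spec, f"doc{d:03d}", chosen))

    result = FixtureResult(kb=kb, documents=tuple(docs))
    if out_dir is not None:
        out_dir = Path(out_dir)
        save_kb(kb, out_dir / "kb")
        docs_dir = out_dir / "docs"
        docs_dir.mkdir(parents=True, exist_ok=True)
        lines = ["doc_id\tstart\tend\ttype\tsurface\tentry_name\ttaxid\tposition\tstatus"]
        for doc in docs:
            (docs_dir / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
            for g in doc.gold:
                lines.append("\t".join([
                    doc.doc_id, str(g.start), str(g.end), g.type, g.surface,
                    g.entry_name or "-",
                    str(g.taxid) if g.taxid is not None else "-",
                    str(g.position) if g.position is not None else "-",
                    g.status or "-",
                ]))
        (out_dir / "gold.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return result


# --------------------------------------------------------------------------
# Scoring against gold
# --------------------------------------------------------------------------

def score_against_gold(
    aset: AnnotationSet, gold: tuple[GoldAnnotation, ...] | list[GoldAnnotation]
) -> dict[str, dict[str, float]]:
    """Exact-span, exact-grounding precision/recall per annotation type.

    A prediction matches a gold annotation when span and type agree and the
    type-specific payload agrees (taxid for species; normalized entry for
    proteins; grounded protein, knowledge-base position and validation status
    for mutations/residues). With zero predictions of a type, precision is
    reported as 1.0 (no prediction was wrong); with zero gold, recall is 1.0.
    """
    preds: dict[str, dict[tuple[int, int], tuple]] = {
        "species": {}, "protein": {}, "mutation": {}, "residue": {},
    }
    for sm in aset.species:
        preds["species"][(sm.span.start, sm.span.end)] = (sm.taxid,)
    for pm in aset.proteins:
        preds["protein"][(pm.span.start, pm.span.end)] = (pm.normalized,)
    for g in aset.grounded:
        kind = "mutation" if hasattr(g.record, "mutant") else "residue"
        preds[kind][(g.record.span.start, g.record.span.end)] = (
            g.protein, g.sequential_position, g.validation.value,
        )

    out: dict[str, dict[str, float]] = {}
    for kind in preds:
        gold_k = [g for g in gold if g.type == kind]
        tp = 0
        for g in gold_k:
            payload = preds[kind].get((g.start, g.end))
            if payload is None:
                continue
            if kind == "species" and payload == (g.taxid,):
                tp += 1
            elif kind == "protein" and payload == (g.entry_name,):
                tp += 1
            elif kind in ("mutation", "residue") and payload == (
                g.entry_name, g.position, g.status
            ):
                tp += 1
        n_pred = len(preds[kind])
        n_gold = len(gold_k)
        out[kind] = {
            "tp": tp,
            "n_pred": n_pred,
            "n_gold": n_gold,
            "precision": tp / n_pred if n_pred else 1.0,
            "recall": tp / n_gold if n_gold else 1.0,
        }
    return out
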