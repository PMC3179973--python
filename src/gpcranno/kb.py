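"""Local protein/species knowledge base.

The knowledge base is a directory standing in for a receptor information
system: reference sequences (``proteins.fasta``), protein metadata with gene
symbols, descriptions and curated synonyms (``proteins.tsv``), species names
mapped to NCBI taxonomy ids (``species.tsv``) and per-protein generic residue
numbering tables (``numbering.tsv``). From it the pipeline builds three
matching dictionaries — gene identifiers, protein identifiers and protein
descriptions — each with its own scoring parameters, plus a species matcher.
"""
from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matching import ScoringParams
from .numbering import GeneralNumber, Scheme, oliveira_number, parse_bw_label

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

KB_FILES = ("proteins.fasta", "proteins.tsv", "species.tsv", "numbering.tsv")


class KBError(ValueError):
    """Raised for missing knowledge-base files or validation failures."""


@dataclass(frozen=True)
class PositionLabels:
    """Generic residue numbers attached to one sequential position."""

    bw: GeneralNumber | None = None
    oliveira: GeneralNumber | None = None


@dataclass
class ProteinEntry:
    """One knowledge-base protein.

    ``entry_name`` follows the Swiss-Prot convention (e.g. ``OPSD_HUMAN``);
    ``numbering`` maps 1-based sequential positions to generic residue
    numbers and is typically partial — only structurally conserved positions
    carry labels.
    """

    entry_name: str
    accession: str
    taxid: int
    gene_symbols: list[str]
    descriptions: list[str]
    synonyms: list[str]
    sequence: str
    numbering: dict[int, PositionLabels] = field(default_factory=dict)

    def residue_at(self, pos: int) -> str:
        """One-letter residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(
                f"{self.entry_name}: position {pos} outside 1..{len(self.sequence)}"
            )
        return self.sequence[pos - 1]

    def validate(self) -> None:
        if not self.sequence:
            raise KBError(f"{self.entry_name}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise KBError(f"{self.entry_name}: invalid residue codes {sorted(bad)}")
        if self.taxid <= 0:
            raise KBError(f"{self.entry_name}: taxid must be positive")
        seen: dict[tuple[Scheme, str], int] = {}
        for pos, labels in self.numbering.items():
            if not 1 <= pos <= len(self.sequence):
                raise KBError(
                    f"{self.entry_name}: numbering position {pos} outside "
                    f"1..{len(self.sequence)}"
                )
            for g in (labels.bw, labels.oliveira):
                if g is None:
                    continue
                key = (g.scheme, g.label)
                if key in seen and seen[key] != pos:
                    raise KBError(
                        f"{self.entry_name}: label {g.label} assigned to both "
                        f"positions {seen[key]} and {pos}"
                    )
                seen[key] = pos


@dataclass(frozen=True)
class SpeciesEntry:
    taxid: int
    names: tuple[str, ...]

    def validate(self) -> None:
        if self.taxid <= 0:
            raise KBError(f"species taxid must be positive: {self.taxid}")
        if not self.names:
            raise KBError(f"species {self.taxid}: no names")


class DictClass(str, enum.Enum):
    GENE_ID = "gene_id"
    PROTEIN_ID = "protein_id"
    DESCRIPTION = "description"


#: Default per-class scoring: identifier classes match exactly up to case;
#: descriptions tolerate 20% weighted edits and Greek/Latin interchange.
DEFAULT_SCORING: dict[DictClass, ScoringParams] = {
    DictClass.GENE_ID: ScoringParams(max_normalized_distance=0.0),
    DictClass.PROTEIN_ID: ScoringParams(max_normalized_distance=0.0),
    DictClass.DESCRIPTION: ScoringParams(
        max_normalized_distance=0.2,
        greek_latin=True,
        substitution_cost_overrides={("-", " "): 0.0},
    ),
}


@dataclass
class Dictionary:
    """Surface strings of one class mapped to the entries that carry them."""

    dclass: DictClass
    entries: dict[str, list[str]]
    scoring: ScoringParams

    def add(self, surface: str, entry_name: str) -> None:
        surface = surface.strip()
        if not surface:
            return
        names = self.entries.setdefault(surface, [])
        if entry_name not in names:
            names.append(entry_name)


@dataclass
class KnowledgeBase:
    proteins: dict[str, ProteinEntry]
    species: dict[int, SpeciesEntry]

    def validate(self) -> None:
        for entry in self.proteins.values():
            entry.validate()
        for sp in self.species.values():
            sp.validate()

    def species_names(self) -> dict[str, int]:
        """Case-folded species name -> taxid."""
        out: dict[str, int] = {}
        for sp in self.species.values():
            for name in sp.names:
                out[name.casefold()] = sp.taxid
        return out


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def _split_pipe(cell: str) -> list[str]:
    cell = cell.strip()
    if not cell or cell == "-":
        return []
    return [p.strip() for p in cell.split("|") if p.strip()]


def load_kb(kb_dir: str | Path) -> KnowledgeBase:
    """Load and fully validate a knowledge-base directory.

    Raises :class:`KBError` naming the offending file/row for missing files,
    duplicate entry names, dangling references, or out-of-range numbering.
    """
    kb_dir = Path(kb_dir)
    for fname in KB_FILES:
        if not (kb_dir / fname).is_file():
            raise KBError(f"missing knowledge-base file: {kb_dir / fname}")

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(kb_dir / "proteins.fasta"), "fasta"):
        if rec.id in sequences:
            raise KBError(f"proteins.fasta: duplicate entry_name {rec.id}")
        sequences[rec.id] = str(rec.seq).upper()

    proteins: dict[str, ProteinEntry] = {}
    with open(kb_dir / "proteins.tsv", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            name = row["entry_name"].strip()
            if name in proteins:
                raise KBError(f"proteins.tsv row {lineno}: duplicate entry_name {name}")
            if name not in sequences:
                raise KBError(
                    f"proteins.tsv row {lineno}: {name} has no sequence in proteins.fasta"
                )
            proteins[name] = ProteinEntry(
                entry_name=name,
                accession=row["accession"].strip(),
                taxid=int(row["taxid"]),
                gene_symbols=_split_pipe(row["gene_symbols"]),
                descriptions=_split_pipe(row["descriptions"]),
                synonyms=_split_pipe(row["synonyms"]),
                sequence=sequences[name],
            )
    unmatched = set(sequences) - set(proteins)
    if unmatched:
        raise KBError(f"proteins.fasta entries missing from proteins.tsv: {sorted(unmatched)}")

    species: dict[int, SpeciesEntry] = {}
    with open(kb_dir / "species.tsv", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            taxid = int(row["taxid"])
            if taxid in species:
                raise KBError(f"species.tsv row {lineno}: duplicate taxid {taxid}")
            species[taxid] = SpeciesEntry(
                taxid=taxid, names=tuple(_split_pipe(row["names"]))
            )

    with open(kb_dir / "numbering.tsv", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            name = row["entry_name"].strip()
            if name not in proteins:
                raise KBError(
                    f"numbering.tsv row {lineno}: unknown entry_name {name}"
                )
            entry = proteins[name]
            pos = int(row["seq_pos"])
            if not 1 <= pos <= len(entry.sequence):
                raise KBError(
                    f"numbering.tsv row {lineno}: position {pos} outside "
                    f"1..{len(entry.sequence)} for {name}"
                )
            bw_raw = row["bw_label"].strip()
            ol_raw = row["oliveira_label"].strip()
            bw = parse_bw_label(bw_raw) if bw_raw and bw_raw != "-" else None
            ol = oliveira_number(int(ol_raw)) if ol_raw and ol_raw != "-" else None
            if pos in entry.numbering:
                raise KBError(
                    f"numbering.tsv row {lineno}: duplicate position {pos} for {name}"
                )
            entry.numbering[pos] = PositionLabels(bw=bw, oliveira=ol)

    kb = KnowledgeBase(proteins=proteins, species=species)
    kb.validate()
    return kb


def save_kb(kb: KnowledgeBase, kb_dir: str | Path) -> None:
    """Write a knowledge base back to its four-file directory layout."""
    kb_dir = Path(kb_dir)
    kb_dir.mkdir(parents=True, exist_ok=True)

    records = [
        SeqRecord(Seq(p.sequence), id=p.entry_name, description="")
        for p in kb.proteins.values()
    ]
    SeqIO.write(records, str(kb_dir / "proteins.fasta"), "fasta")

    with open(kb_dir / "proteins.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["entry_name", "accession", "taxid", "gene_symbols", "descriptions", "synonyms"]
        )
        for p in kb.proteins.values():
            w.writerow([
                p.entry_name, p.accession, p.taxid,
                "|".join(p.gene_symbols), "|".join(p.descriptions),
                "|".join(p.synonyms),
            ])

    with open(kb_dir / "species.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["taxid", "names"])
        for sp in kb.species.values():
            w.writerow([sp.taxid, "|".join(sp.names)])

    with open(kb_dir / "numbering.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["entry_name", "seq_pos", "bw_label", "oliveira_label"])
        for p in kb.proteins.values():
            for pos in sorted(p.numbering):
                labels = p.numbering[pos]
                w.writerow([
                    p.entry_name, pos,
                    labels.bw.label if labels.bw else "-",
                    labels.oliveira.label if labels.oliveira else "-",
                ])


# --------------------------------------------------------------------------
# Dictionaries
# --------------------------------------------------------------------------

def build_dictionaries(
    kb: KnowledgeBase,
    scoring: dict[DictClass, ScoringParams] | None = None,
) -> list[Dictionary]:
    """Build the gene-id, protein-id and description dictionaries.

    Curated synonyms are merged into the description dictionary (they share
    its free-text nature and tolerant scoring). Each surface string maps to
    every entry that carries it, so shared names like "rhodopsin" stay
    ambiguous until species context resolves them.
    """
    scoring = scoring or DEFAULT_SCORING
    gene = Dictionary(DictClass.GENE_ID, {}, scoring[DictClass.GENE_ID])
    prot = Dictionary(DictClass.PROTEIN_ID, {}, scoring[DictClass.PROTEIN_ID])
    desc = Dictionary(DictClass.DESCRIPTION, {}, scoring[DictClass.DESCRIPTION])
    for p in kb.proteins.values():
        for sym in p.gene_symbols:
            gene.add(sym, p.entry_name)
        prot.add(p.entry_name, p.entry_name)
        if p.accession:
            prot.add(p.accession, p.entry_name)
        for d in p.descriptions:
            desc.add(d, p.entry_name)
        for syn in p.synonyms:
            desc.add(syn, p.entry_name)
    return [gene, prot, desc]


class SpeciesMatcher:
    """Exact, case-insensitive, word-boundary matcher over species names."""

    def __init__(self, kb: KnowledgeBase):
        self._names = kb.species_names()
        alts = sorted(self._names, key=len, reverse=True)
        if alts:
            pattern = r"\b(?:%s)\b" % "|".join(re.escape(n) for n in alts)
            self._re: re.Pattern[str] | None = re.compile(pattern, re.IGNORECASE)
        else:  # pragma: no cover - empty KB
            self._re = None

    def lookup(self, name: str) -> int | None:
        return self._names.get(name.casefold())

    def finditer(self, text: str):
        if self._re is None:  # pragma: no cover
            return
        for m in self._re.finditer(text):
            yield m.start(), m.end(), self._names[m.group().casefold()]


def species_dictionary(kb: KnowledgeBase) -> SpeciesMatcher:
    """The species matcher for a loaded knowledge base."""
    return SpeciesMatcher(kb)
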