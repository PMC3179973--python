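import random

import pytest

from gpcranno.kb import (
    KnowledgeBase,
    PositionLabels,
    ProteinEntry,
    SpeciesEntry,
)
from gpcranno.numbering import GeneralNumber, Scheme, oliveira_number

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: random.Random, length: int, fixed: dict[int, str] | None = None) -> str:
    seq = [rng.choice(AA) for _ in range(length)]
    for pos, aa in (fixed or {}).items():
        seq[pos - 1] = aa
    return "".join(seq)


def bw(helix: int, index: int) -> GeneralNumber:
    return GeneralNumber(scheme=Scheme.BALLESTEROS_WEINSTEIN, helix=helix, index=index)


@pytest.fixture
def rhodopsin_kb() -> KnowledgeBase:
    """Two rhodopsins (human, bovine) sharing the description "rhodopsin".

    Human rhodopsin carries D at 98 and W at 161, and maps position 131 to
    Ballesteros-Weinstein 3.50 / Oliveira 160.
    """
    rng = random.Random(42)
    proteins = {}
    for entry_name, taxid, fixed in [
        ("OPSD_HUMAN", 9606, {98: "D", 161: "W", 131: "R"}),
        ("OPSD_BOVIN", 9913, {98: "K", 161: "F", 131: "R"}),
    ]:
        proteins[entry_name] = ProteinEntry(
            entry_name=entry_name,
            accession=f"P{rng.randint(0, 99999):05d}",
            taxid=taxid,
            gene_symbols=["RHO"],
            descriptions=["rhodopsin"],
            synonyms=[],
            sequence=random_sequence(rng, 348, fixed),
            numbering={131: PositionLabels(bw=bw(3, 50), oliveira=oliveira_number(160))},
        )
    species = {
        9606: SpeciesEntry(taxid=9606, names=("human", "Homo sapiens")),
        9913: SpeciesEntry(taxid=9913, names=("bovine", "Bos taurus")),
    }
    kb = KnowledgeBase(proteins=proteins, species=species)
    kb.validate()
    return kb


@pytest.fixture
def h1_kb() -> KnowledgeBase:
    """Synthetic one-protein KB: guinea-pig histamine H1 with Trp at 161."""
    rng = random.Random(7)
    entry = ProteinEntry(
        entry_name="HRH1_CAVPO",
        accession="P30546",
        taxid=10141,
        gene_symbols=["HRH1"],
        descriptions=["histamine H1 receptor"],
        synonyms=["H1R"],
        sequence=random_sequence(rng, 420, {161: "W"}),
        numbering={161: PositionLabels(bw=bw(4, 56), oliveira=oliveira_number(137))},
    )
    kb = KnowledgeBase(
        proteins={entry.entry_name: entry},
        species={10141: SpeciesEntry(taxid=10141, names=("guinea pig", "Cavia porcellus"))},
    )
    kb.validate()
    return kb
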