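import random

import pytest

from _oracles import oracle_ground_all, oracle_offset
from gpcranno.fixtures import FixtureSpec, generate
from gpcranno.grammar import MutationRecord, ResidueRecord, find_mutation_mentions, find_residue_mentions
from gpcranno.grounding import (
    OffsetSolution,
    Validation,
    general_to_sequential,
    ground_all,
    ground_record,
    resolve_offset,
    sequential_to_general,
)
from gpcranno.kb import KnowledgeBase, ProteinEntry, save_kb
from gpcranno.numbering import Scheme, parse_bw_label
from gpcranno.pipeline import Annotator
from gpcranno.segmentation import Mention, segment


def _entry(seq: str, name: str = "TEST_HUMAN") -> ProteinEntry:
    return ProteinEntry(
        entry_name=name, accession="P00001", taxid=9606,
        gene_symbols=[], descriptions=["test receptor"], synonyms=[],
        sequence=seq,
    )


def _record(wt: str, pos: int, mut: str = "A") -> MutationRecord:
    return MutationRecord(
        wild_type=wt, position=pos, mutant=mut,
        scheme=Scheme.SEQUENTIAL, span=Mention(0, 4, "x"),
    )


# --------------------------------------------------------------------------
# Worked example and failure paths
# --------------------------------------------------------------------------

def test_trp161_in_human_rhodopsin_grounds_validated(rhodopsin_kb):
    aset = Annotator(rhodopsin_kb).annotate(
        "Trp161 in human rhodopsin plays an important role."
    )
    (g,) = aset.grounded
    assert g.protein == "OPSD_HUMAN"
    assert g.sequential_position == 161
    assert g.validation is Validation.VALIDATED
    assert g.applied_offset == 0
    assert g.same_sentence is True


def test_out_of_reach_position_stays_unvalidated(rhodopsin_kb):
    aset = Annotator(rhodopsin_kb).annotate(
        "Cys999 in human rhodopsin was probed."
    )
    (g,) = aset.grounded
    assert g.validation is Validation.UNVALIDATED
    assert g.protein == "OPSD_HUMAN"
    assert g.sequential_position is None  # outside the sequence at any offset


def test_record_with_no_protein_in_document_is_ungrounded(rhodopsin_kb):
    aset = Annotator(rhodopsin_kb).annotate("The W161A mutant was inactive.")
    (g,) = aset.grounded
    assert g.protein == ""
    assert g.validation is Validation.UNVALIDATED


# --------------------------------------------------------------------------
# Numbering conversion
# --------------------------------------------------------------------------

def test_general_sequential_round_trip_on_fixture_kb(tmp_path):
    kb = generate(FixtureSpec(seed=5, n_proteins=4), out_dir=tmp_path).kb
    for entry in kb.proteins.values():
        for pos, labels in entry.numbering.items():
            for g in (labels.bw, labels.oliveira):
                assert general_to_sequential(entry, g) == pos
            bw, ol = sequential_to_general(entry, pos)
            assert (bw, ol) == (labels.bw.label, labels.oliveira.label)
    # file-vs-API sweep over the serialized numbering table
    rows = (tmp_path / "kb" / "numbering.tsv").read_text().splitlines()[1:]
    for row in rows:
        name, pos, bw_label, ol_label = row.split("\t")
        bw, ol = sequential_to_general(kb.proteins[name], int(pos))
        assert (bw or "-") == bw_label and (ol or "-") == ol_label


def test_unmapped_position_has_no_general_numbers(rhodopsin_kb):
    entry = rhodopsin_kb.proteins["OPSD_HUMAN"]
    assert sequential_to_general(entry, 131) == ("3.50", "160")
    assert sequential_to_general(entry, 5) == (None, None)
    assert general_to_sequential(entry, parse_bw_label("3.50")) == 131
    assert general_to_sequential(entry, parse_bw_label("7.50")) is None
    with pytest.raises(IndexError):
        sequential_to_general(entry, 0)


# --------------------------------------------------------------------------
# Offset resolution
# --------------------------------------------------------------------------

def test_resolver_recovers_planted_offset():
    rng = random.Random(31)
    seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(360))
    entry = _entry(seq)
    positions = [40, 150, 300]
    records = [_record(seq[p - 1], p + 24) for p in positions]
    sol = resolve_offset(entry, records)
    assert sol is not None
    assert sol.offset == 24
    assert sol.n_consistent == 3
    assert 24 in sol.candidates_considered


def test_offset_zero_wins_when_records_already_consistent():
    entry = _entry("A" * 60)
    sol = resolve_offset(entry, [_record("A", 10)])
    # every offset fits a poly-A sequence; minimal |delta| must win
    assert sol.offset == 0
    assert sol.offset == oracle_offset(entry, [_record("A", 10)], 200)


def test_exact_magnitude_tie_prefers_positive_offset():
    seq = list("G" * 30)
    seq[4] = seq[14] = "W"  # positions 5 and 15
    entry = _entry("".join(seq))
    sol = resolve_offset(entry, [_record("W", 10)])
    assert sol.offset == 5  # +5 and -5 both explain the record
    assert set(sol.candidates_considered) == {5, -5}


def test_no_admissible_offset_returns_none():
    entry = _entry("G" * 30)
    assert resolve_offset(entry, [_record("W", 10)]) is None


def test_single_record_offset_equals_bruteforce_enumeration():
    rng = random.Random(37)
    for _ in range(25):
        seq = "".join(rng.choice("ACDE") for _ in range(rng.randint(30, 80)))
        rec = _record(rng.choice("ACDE"), rng.randint(1, 100))
        sol = resolve_offset(_entry(seq), [rec])
        want = oracle_offset(_entry(seq), [rec], 200)
        assert (sol.offset if sol else None) == want


def test_offset_applied_retroactively_to_bare_number_record(rhodopsin_kb):
    aset = Annotator(rhodopsin_kb).annotate("human rhodopsin was expressed.")
    (pm,) = [p for p in aset.proteins if p.normalized == "OPSD_HUMAN"]
    _, tokens = segment("human rhodopsin was expressed.")
    sentences, _ = segment("human rhodopsin was expressed.")
    bare = ResidueRecord(
        amino_acid=None, position=300, scheme=Scheme.SEQUENTIAL,
        span=Mention(16, 19, "was"),
    )
    sol = OffsetSolution(offset=24, n_consistent=2, candidates_considered=(24,))
    g = ground_record(bare, [pm], tokens, sentences, rhodopsin_kb,
                      offsets={"OPSD_HUMAN": sol})
    assert g.sequential_position == 276
    assert g.applied_offset == 24
    assert g.validation is Validation.CORRECTED_BY_OFFSET


# --------------------------------------------------------------------------
# Ranking properties
# --------------------------------------------------------------------------

def test_same_sentence_protein_outranks_nearer_cross_sentence_protein(rhodopsin_kb):
    # Arg131 is shared by both rhodopsins, so ranking alone decides; the
    # bovine mention is closer in tokens but sits in the next sentence.
    text = (
        "The human rhodopsin story is long and complicated and in many "
        "respects hinges on residue Arg131. Nearby bovine rhodopsin differs."
    )
    aset = Annotator(rhodopsin_kb).annotate(text)
    (g,) = aset.grounded
    assert g.protein == "OPSD_HUMAN"
    assert g.same_sentence is True


def test_grounding_decisions_match_bruteforce_oracle_on_fixture_docs():
    rng = random.Random(41)
    for case in range(40):
        spec = FixtureSpec(
            seed=1000 + case,
            n_proteins=rng.randint(2, 5),
            n_species=rng.randint(2, 3),
            proteins_per_document=rng.randint(1, 3),
            n_mutation_mentions=rng.randint(1, 3),
            n_residue_mentions=2,
            distractor_density=0.3,
            same_sentence_fraction=0.6,
        )
        res = generate(spec)
        ann = Annotator(res.kb)
        for doc in res.documents:
            sentences, tokens = segment(doc.text)
            aset = ann.annotate(doc.text, doc_id=doc.doc_id)
            records = [g.record for g in aset.grounded]
            got = [
                (g.protein, g.sequential_position, g.applied_offset,
                 g.validation.value)
                for g in aset.grounded
            ]
            want = oracle_ground_all(
                records, aset.proteins, tokens, sentences, res.kb
            )
            assert got == want


def test_validation_soundness_over_fixture_runs():
    for seed, offset in [(1, 0), (2, 24), (3, -120)]:
        res = generate(FixtureSpec(seed=seed, planted_offset=offset, n_documents=3))
        ann = Annotator(res.kb)
        for doc in res.documents:
            for g in ann.annotate(doc.text).grounded:
                if g.validation in (Validation.VALIDATED, Validation.CORRECTED_BY_OFFSET):
                    entry = res.kb.proteins[g.protein]
                    aa = getattr(g.record, "wild_type", None) or \
                        getattr(g.record, "amino_acid", None)
                    if aa is not None:
                        assert entry.residue_at(g.sequential_position) == aa
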