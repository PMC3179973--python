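import pytest

from gpcranno.fixtures import (
    FixtureSpec,
    GenerationError,
    GoldAnnotation,
    generate,
    score_against_gold,
)
from gpcranno.grammar import find_mutation_mentions
from gpcranno.pipeline import Annotator


def test_same_seed_reproduces_identical_bytes_different_seed_differs():
    a = generate(FixtureSpec(seed=4, n_documents=2))
    b = generate(FixtureSpec(seed=4, n_documents=2))
    c = generate(FixtureSpec(seed=5, n_documents=2))
    assert [d.text for d in a.documents] == [d.text for d in b.documents]
    assert a.kb == b.kb
    assert [d.text for d in a.documents] != [d.text for d in c.documents]


@pytest.mark.parametrize("offset,status", [(0, "validated"), (24, "corrected_by_offset")])
def test_gold_mutation_status_reflects_planted_offset(offset, status):
    res = generate(FixtureSpec(seed=2, planted_offset=offset))
    golds = [g for d in res.documents for g in d.gold if g.type == "mutation"]
    assert golds
    assert {g.status for g in golds} == {status}


def test_gold_spans_and_positions_are_self_consistent():
    res = generate(FixtureSpec(seed=11, planted_offset=30, n_documents=2))
    for doc in res.documents:
        for g in doc.gold:
            assert doc.text[g.start:g.end] == g.surface
            if g.type == "mutation":
                (rec,) = find_mutation_mentions(g.surface)
                entry = res.kb.proteins[g.entry_name]
                # planted wild type sits at the gold KB position
                assert entry.residue_at(g.position) == rec.wild_type
                assert rec.position == g.position + 30


@pytest.mark.parametrize("kwargs", [
    {"n_species": 0},
    {"n_proteins": 0},
    {"n_proteins": 99},
    {"planted_offset": 500},
    {"notation_mix": (1.0, 1.0)},
    {"bw_coverage": 2.0},
])
def test_infeasible_specs_raise_generation_error(kwargs):
    with pytest.raises(GenerationError):
        FixtureSpec(seed=0, **kwargs).validate()


def test_perfect_pipeline_output_scores_one(h1_kb):
    res = generate(FixtureSpec(seed=6))
    doc = res.documents[0]
    aset = Annotator(res.kb).annotate(doc.text, doc_id=doc.doc_id)
    scores = score_against_gold(aset, doc.gold)
    for kind in ("species", "protein", "mutation", "residue"):
        assert scores[kind]["precision"] == 1.0
        assert scores[kind]["recall"] == 1.0


def test_empty_output_scores_zero_recall_unit_precision():
    res = generate(FixtureSpec(seed=6))
    doc = res.documents[0]
    empty = Annotator(res.kb).annotate("", doc_id=doc.doc_id)
    scores = score_against_gold(empty, doc.gold)
    assert scores["mutation"]["recall"] == 0.0
    assert scores["mutation"]["precision"] == 1.0  # zero predictions convention


def test_scores_agree_with_hand_counts_on_micro_fixture():
    gold = [
        GoldAnnotation(0, 5, "species", "human", taxid=9606),
        GoldAnnotation(6, 15, "protein", "rhodopsin", entry_name="OPSD_HUMAN"),
        GoldAnnotation(20, 26, "residue", "Trp161", entry_name="OPSD_HUMAN",
                       position=161, status="validated"),
        GoldAnnotation(30, 34, "mutation", "D98F", entry_name="OPSD_HUMAN",
                       position=98, status="validated"),
        GoldAnnotation(40, 44, "mutation", "K99A", entry_name="OPSD_HUMAN",
                       position=99, status="validated"),
    ]
    from gpcranno.pipeline import AnnotationSet
    from gpcranno.ner import SpeciesMention
    from gpcranno.segmentation import Mention
    from gpcranno.grammar import MutationRecord
    from gpcranno.grounding import GroundedAnnotation, Validation
    from gpcranno.numbering import Scheme

    aset = AnnotationSet(doc_id="m", text_sha256="0" * 64,
                         pipeline_version="x", config_digest="0" * 64)
    aset.species.append(SpeciesMention(span=Mention(0, 5, "human"), taxid=9606))
    # one correct mutation, one grounded to the wrong position
    for (s, e, t, pos) in [(30, 34, "D98F", 98), (40, 44, "K99A", 17)]:
        aset.grounded.append(GroundedAnnotation(
            record=MutationRecord("D", 98, "F", Scheme.SEQUENTIAL, Mention(s, e, t)),
            protein="OPSD_HUMAN", sequential_position=pos, applied_offset=0,
            validation=Validation.VALIDATED,
        ))
    scores = score_against_gold(aset, gold)
    assert scores["species"] == {"tp": 1, "n_pred": 1, "n_gold": 1,
                                 "precision": 1.0, "recall": 1.0}
    assert scores["protein"]["tp"] == 0 and scores["protein"]["recall"] == 0.0
    assert scores["mutation"]["tp"] == 1
    assert scores["mutation"]["precision"] == 0.5
    assert scores["mutation"]["recall"] == 0.5
    assert scores["residue"]["recall"] == 0.0


def test_generated_files_on_disk(tmp_path):
    res = generate(FixtureSpec(seed=8, n_documents=3), out_dir=tmp_path)
    assert (tmp_path / "kb" / "proteins.fasta").exists()
    docs = sorted(p.name for p in (tmp_path / "docs").iterdir())
    assert docs == ["doc000.txt", "doc001.txt", "doc002.txt"]
    gold_lines = (tmp_path / "gold.tsv").read_text().splitlines()
    assert len(gold_lines) == 1 + sum(len(d.gold) for d in res.documents)
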