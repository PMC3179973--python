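"""End-to-end document annotation and standoff serialization.

``annotate_document`` runs segmentation → species/protein NER →
normalization → mutation/residue grammar → grounding, and assembles an
:class:`AnnotationSet`: all mentions as character spans into the unmodified
source text (standoff annotation), serializable to JSON (full nested
structure) or TSV (one row per annotation). Output is deterministic given
(text, knowledge base, config): identical inputs yield byte-identical JSON.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .grammar import (
    MutationRecord,
    ResidueRecord,
    find_mutation_mentions,
    find_residue_mentions,
)
from .grounding import GroundedAnnotation, Validation, ground_all
from .kb import KnowledgeBase, build_dictionaries, species_dictionary
from .ner import (
    ProteinMention,
    SpeciesMention,
    find_protein_mentions,
    find_species_mentions,
    normalize_protein,
)
from .numbering import GeneralNumber, Scheme, oliveira_number, parse_bw_label
from .segmentation import Mention, segment


@dataclass
class AnnotationSet:
    """All annotations for one document, plus provenance and counts."""

    doc_id: str
    text_sha256: str
    pipeline_version: str
    config_digest: str
    species: list[SpeciesMention] = field(default_factory=list)
    proteins: list[ProteinMention] = field(default_factory=list)
    grounded: list[GroundedAnnotation] = field(default_factory=list)

    @property
    def stats(self) -> dict[str, int]:
        return {
            "species": len(self.species),
            "proteins": len(self.proteins),
            "proteins_normalized": sum(
                1 for p in self.proteins if p.normalized is not None
            ),
            "mutations": sum(
                1 for g in self.grounded if isinstance(g.record, MutationRecord)
            ),
            "residues": sum(
                1 for g in self.grounded if isinstance(g.record, ResidueRecord)
            ),
            "grounded": sum(1 for g in self.grounded if g.protein),
            "validated": sum(
                1 for g in self.grounded
                if g.validation is not Validation.UNVALIDATED
            ),
        }

    def __len__(self) -> int:
        return len(self.species) + len(self.proteins) + len(self.grounded)


class Annotator:
    """Reusable pipeline bound to one knowledge base and configuration."""

    def __init__(self, kb: KnowledgeBase, config: PipelineConfig | None = None):
        self.kb = kb
        self.config = config or PipelineConfig()
        self.dictionaries = build_dictionaries(
            kb, scoring=self.config.scoring_params()
        )
        self.species_matcher = species_dictionary(kb)

    def annotate(self, text: str, doc_id: str = "doc") -> AnnotationSet:
        cfg = self.config
        sentences, tokens = segment(text)
        species = find_species_mentions(text, self.species_matcher)
        proteins = [
            normalize_protein(pm, species, tokens, self.kb)
            for pm in find_protein_mentions(text, self.dictionaries, tokens)
        ]
        mutations = find_mutation_mentions(text, sentences)
        residues = find_residue_mentions(
            text,
            sentences,
            mutation_spans=[m.span for m in mutations],
            bw_cue_words=frozenset(cfg.grammar.bw_cue_words),
            unit_blocklist=frozenset(cfg.grammar.unit_blocklist),
            oliveira_enabled=cfg.grammar.oliveira_enabled,
        )
        records = sorted(
            [*mutations, *residues], key=lambda r: (r.span.start, r.span.end)
        )
        grounded = ground_all(
            records, proteins, tokens, sentences, self.kb,
            window=cfg.grounding.offset_window,
        )
        return AnnotationSet(
            doc_id=doc_id,
            text_sha256=hashlib.sha256(text.encode("utf-8")).hexdigest(),
            pipeline_version=__version__,
            config_digest=cfg.digest(),
            species=species,
            proteins=proteins,
            grounded=grounded,
        )


def annotate_document(
    text: str,
    kb: KnowledgeBase,
    config: PipelineConfig | None = None,
    doc_id: str = "doc",
) -> AnnotationSet:
    """One-shot convenience wrapper around :class:`Annotator`."""
    return Annotator(kb, config).annotate(text, doc_id=doc_id)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

_ABSENT = "-"


def _span_dict(span: Mention) -> dict:
    return {"start": span.start, "end": span.end, "surface": span.text}


def _record_dict(rec: MutationRecord | ResidueRecord) -> dict:
    out = _span_dict(rec.span)
    out["scheme"] = rec.scheme.value
    out["article_position"] = rec.position
    if isinstance(rec, MutationRecord):
        out["kind"] = "mutation"
        out["wild_type"] = rec.wild_type
        out["mutant"] = rec.mutant
        out["silent"] = rec.silent
    else:
        out["kind"] = "residue"
        out["amino_acid"] = rec.amino_acid
    if rec.general is not None:
        out["general_label"] = rec.general.label
    return out


def aset_to_dict(aset: AnnotationSet) -> dict:
    annotations: list[dict] = []
    for sm in aset.species:
        annotations.append({"type": "species", **_span_dict(sm.span), "taxid": sm.taxid})
    for pm in aset.proteins:
        annotations.append({
            "type": "protein",
            **_span_dict(pm.span),
            "dclass": pm.dclass.value,
            "candidates": [[name, score] for name, score in pm.candidates],
            "normalized": pm.normalized,
            "resolving_species": pm.resolving_species,
        })
    for g in aset.grounded:
        rec_dict = _record_dict(g.record)
        annotations.append({
            "type": rec_dict["kind"],
            **rec_dict,
            "protein": g.protein,
            "sequential_position": g.sequential_position,
            "applied_offset": g.applied_offset,
            "bw_label": g.bw_label,
            "oliveira_label": g.oliveira_label,
            "validation": g.validation.value,
            "grounding_distance": g.grounding_distance,
            "same_sentence": g.same_sentence,
        })
    return {
        "doc_id": aset.doc_id,
        "text_sha256": aset.text_sha256,
        "pipeline_version": aset.pipeline_version,
        "config_digest": aset.config_digest,
        "stats": aset.stats,
        "annotations": annotations,
    }


def _general_from(d: dict) -> GeneralNumber | None:
    label = d.get("general_label")
    if label is None:
        return None
    if d["scheme"] == Scheme.BALLESTEROS_WEINSTEIN.value:
        return parse_bw_label(label)
    return oliveira_number(int(label))


def _record_from(d: dict) -> MutationRecord | ResidueRecord:
    span = Mention(d["start"], d["end"], d["surface"])
    scheme = Scheme(d["scheme"])
    if d["kind"] == "mutation":
        return MutationRecord(
            wild_type=d["wild_type"], position=d["article_position"],
            mutant=d["mutant"], scheme=scheme, span=span,
            general=_general_from(d), silent=d["silent"],
        )
    return ResidueRecord(
        amino_acid=d["amino_acid"], position=d["article_position"],
        scheme=scheme, span=span, general=_general_from(d),
    )


def aset_from_dict(data: dict) -> AnnotationSet:
    from .kb import DictClass  # local to avoid cycle noise in module header

    aset = AnnotationSet(
        doc_id=data["doc_id"],
        text_sha256=data["text_sha256"],
        pipeline_version=data["pipeline_version"],
        config_digest=data["config_digest"],
    )
    for a in data["annotations"]:
        span = Mention(a["start"], a["end"], a["surface"])
        if a["type"] == "species":
            aset.species.append(SpeciesMention(span=span, taxid=a["taxid"]))
        elif a["type"] == "protein":
            aset.proteins.append(ProteinMention(
                span=span,
                dclass=DictClass(a["dclass"]),
                candidates=tuple((n, s) for n, s in a["candidates"]),
                normalized=a["normalized"],
                resolving_species=a["resolving_species"],
            ))
        else:
            aset.grounded.append(GroundedAnnotation(
                record=_record_from(a),
                protein=a["protein"],
                sequential_position=a["sequential_position"],
                applied_offset=a["applied_offset"],
                validation=Validation(a["validation"]),
                bw_label=a["bw_label"],
                oliveira_label=a["oliveira_label"],
                grounding_distance=a["grounding_distance"],
                same_sentence=a["same_sentence"],
            ))
    return aset


def to_json(aset: AnnotationSet) -> str:
    return json.dumps(aset_to_dict(aset), sort_keys=True, indent=2,
                      ensure_ascii=False) + "\n"


TSV_COLUMNS = [
    "doc_id", "start", "end", "type", "surface", "protein",
    "sequential_position", "applied_offset", "bw_label", "oliveira_label",
    "validation",
]


def to_tsv(aset: AnnotationSet) -> str:
    def cell(v) -> str:
        return _ABSENT if v in (None, "") else str(v)

    lines = ["\t".join(TSV_COLUMNS)]
    data = aset_to_dict(aset)
    for a in data["annotations"]:
        lines.append("\t".join([
            aset.doc_id,
            str(a["start"]), str(a["end"]), a["type"],
            a["surface"].replace("\t", " ").replace("\n", " "),
            cell(a.get("protein") or a.get("normalized")),
            cell(a.get("sequential_position")),
            cell(a.get("applied_offset")),
            cell(a.get("bw_label")),
            cell(a.get("oliveira_label")),
            cell(a.get("validation")),
        ]))
    return "\n".join(lines) + "\n"


def write_annotations(
    aset: AnnotationSet, path: str | Path, format: str = "json"
) -> Path:
    path = Path(path)
    if format == "json":
        path.write_text(to_json(aset), encoding="utf-8")
    elif format == "tsv":
        path.write_text(to_tsv(aset), encoding="utf-8")
    else:
        raise ValueError(f"unknown format: {format!r}")
    return path


def read_annotations(path: str | Path) -> AnnotationSet:
    with open(path, encoding="utf-8") as fh:
        return aset_from_dict(json.load(fh))
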