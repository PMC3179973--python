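"""Pipeline configuration: scoring thresholds, grammar toggles, grounding.

All defaults are overridable from a YAML file; ``gpcranno config show``
prints the full effective default set.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .grammar import DEFAULT_BW_CUE_WORDS, DEFAULT_UNIT_BLOCKLIST
from .grounding import DEFAULT_OFFSET_WINDOW
from .kb import DictClass
from .matching import ScoringParams


@dataclass(frozen=True)
class GrammarConfig:
    oliveira_enabled: bool = True
    bw_cue_words: tuple[str, ...] = tuple(sorted(DEFAULT_BW_CUE_WORDS))
    unit_blocklist: tuple[str, ...] = tuple(sorted(DEFAULT_UNIT_BLOCKLIST))


@dataclass(frozen=True)
class GroundingConfig:
    offset_window: int = DEFAULT_OFFSET_WINDOW
    #: species context scope for normalization; "document" is the default
    #: (a species mentioned anywhere can resolve a protein)
    species_scope: str = "document"


@dataclass(frozen=True)
class ScoringConfig:
    gene_id_max_distance: float = 0.0
    protein_id_max_distance: float = 0.0
    description_max_distance: float = 0.2
    case_sensitive: bool = False
    greek_latin_descriptions: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    grammar: GrammarConfig = field(default_factory=GrammarConfig)
    grounding: GroundingConfig = field(default_factory=GroundingConfig)

    def scoring_params(self) -> dict[DictClass, ScoringParams]:
        s = self.scoring
        return {
            DictClass.GENE_ID: ScoringParams(
                max_normalized_distance=s.gene_id_max_distance,
                case_sensitive=s.case_sensitive,
            ),
            DictClass.PROTEIN_ID: ScoringParams(
                max_normalized_distance=s.protein_id_max_distance,
                case_sensitive=s.case_sensitive,
            ),
            DictClass.DESCRIPTION: ScoringParams(
                max_normalized_distance=s.description_max_distance,
                case_sensitive=s.case_sensitive,
                greek_latin=s.greek_latin_descriptions,
                substitution_cost_overrides={("-", " "): 0.0},
            ),
        }

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(
            scoring=ScoringConfig(**data.get("scoring", {})),
            grammar=GrammarConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in data.get("grammar", {}).items()
            }),
            grounding=GroundingConfig(**data.get("grounding", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
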