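"""Approximate string matching for dictionary lookup.

Each dictionary class (gene identifiers, protein identifiers, protein
descriptions) carries its own scoring parameters: identifier classes demand
exact matches up to case, while free-text descriptions tolerate a fraction of
weighted edit operations and treat Greek letters and their spelled-out Latin
names as interchangeable (β2-adrenergic ≡ beta2-adrenergic).

The score of a (surface, key) pair is ``1 - d / max(|a|, |b|)`` where ``d``
is a weighted Damerau-Levenshtein distance computed on canonicalized strings
and lengths are measured after canonicalization. Canonicalization case-folds
(unless the class is case-sensitive), collapses whitespace runs, and spells
out Greek letters; residual 1:1 substitution-cost overrides (e.g. hyphen vs
space at cost 0) come from the scoring parameters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

GREEK_TO_LATIN = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "µ": "mu", "ν": "nu", "ξ": "xi", "π": "pi",
    "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau", "υ": "upsilon",
    "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}


@dataclass(frozen=True)
class ScoringParams:
    """Per-dictionary-class matching parameters.

    ``max_normalized_distance`` is the tolerated fraction of weighted edits
    (0.0 = exact after canonicalization). ``substitution_cost_overrides``
    maps unordered character pairs to a cost in [0, 1]; pairs not listed cost
    1. ``greek_latin`` enables spelling out Greek letters before comparison.
    """

    max_normalized_distance: float = 0.0
    case_sensitive: bool = False
    greek_latin: bool = False
    substitution_cost_overrides: dict[tuple[str, str], float] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_normalized_distance <= 1.0:
            raise ValueError("max_normalized_distance must be in [0, 1]")
        if any(c < 0 for c in self.substitution_cost_overrides.values()):
            raise ValueError("substitution costs must be >= 0")

    def canonicalize(self, s: str) -> str:
        if not self.case_sensitive:
            s = s.casefold()
        if self.greek_latin:
            s = "".join(GREEK_TO_LATIN.get(ch, ch) for ch in s)
        return " ".join(s.split())

    def substitution_cost(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        ov = self.substitution_cost_overrides
        return ov.get((a, b), ov.get((b, a), 1.0))


def weighted_edit_distance(a: str, b: str, params: ScoringParams) -> float:
    """Weighted Damerau-Levenshtein distance between canonicalized strings.

    Insertions and deletions cost 1; substitutions cost 1 unless overridden;
    adjacent transpositions cost 1.
    """
    a = params.canonicalize(a)
    b = params.canonicalize(b)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return float(n or m)
    prev2: list[float] = []
    prev = [float(j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [float(i)] + [0.0] * m
        for j in range(1, m + 1):
            cost = params.substitution_cost(a[i - 1], b[j - 1])
            best = min(prev[j] + 1.0, cur[j - 1] + 1.0, prev[j - 1] + cost)
            if (
                i > 1 and j > 1
                and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]
                and a[i - 1] != a[i - 2]
            ):
                best = min(best, prev2[j - 2] + 1.0)
            cur[j] = best
        prev2, prev = prev, cur
    return prev[m]


def match_score(surface: str, key: str, params: ScoringParams) -> float:
    """Similarity in [0, 1]; 1.0 means exact after canonicalization."""
    ca = params.canonicalize(surface)
    cb = params.canonicalize(key)
    if ca == cb:
        return 1.0
    longest = max(len(ca), len(cb))
    if longest == 0:
        return 1.0
    d = weighted_edit_distance(surface, key, params)
    return max(0.0, 1.0 - d / longest)


def accepts(surface: str, key: str, params: ScoringParams) -> bool:
    return match_score(surface, key, params) >= 1.0 - params.max_normalized_distance - 1e-9
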