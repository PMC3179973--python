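# Methods

This note documents the models, heuristics, defaults and numerical choices
behind `gpcranno`, and what its synthetic fixtures do and do not show about
real articles.

## Coordinate system

Document character offsets are 0-based half-open spans into the unmodified
source text (standoff annotation); sequence positions are 1-based, matching
the biological convention ("position 98" is `sequence[97]` in Python).
Sentences and tokens come from a deterministic rule-based segmenter: a
sentence ends at `.`/`!`/`?` followed by whitespace and an uppercase/digit
start, with an abbreviation stop-list (`Fig.`, `et al.`, `e.g.`, `p.`, …);
decimal numbers — which include Ballesteros-Weinstein labels like `3.50` —
never split because the period is not followed by whitespace. Tokens are
alphanumeric runs, decimal numbers, arrow glyphs (`→`, `->`, `-->`) and
single punctuation characters. The word-distance between two mentions is the
number of tokens strictly between them (0 for adjacent mentions, symmetric);
this is the unit used for all proximity reasoning. De-hyphenation of
line-broken words and multi-column reflow are upstream concerns of text
extraction and are not handled (known limitation).

## Mention grammar

The mutation grammar covers six notation families around the `XnY` theme:
compact one-letter (`D98F`), compact three-letter (`Asp98Phe`), arrow
(`Asp98 → Phe`, any of the three arrow glyphs, optional spaces), hyphen with
repeated position (`Asp98-Phe98`; disagreeing positions such as `Asp98-Phe99`
are rejected and logged), "to" (`D98 to phenylalanine`) and verbal (`Asp 98
was mutated/substituted/replaced/changed to …`). Amino acids are accepted as
one-letter codes, three-letter codes in any capitalization, and full names
(including `aspartate`/`glutamate`); everything canonicalizes to one-letter
codes. Overlapping matches are resolved longest-span-first. Silent
substitutions (wild type = mutant) are kept and flagged.

Precision guards, each chosen because common article furniture would
otherwise parse as a mention:

- compact mutations with single-letter codes on **both** sides require a
  two-digit position, so receptor synonyms (`H1R`) and fusion partners
  (`T4` lysozyme) never parse; positions 1–9 remain reachable through every
  other family;
- single-letter residue mentions (`W161`) likewise require two digits;
- bare Ballesteros-Weinstein labels are accepted only with a cue word
  (`residue`, `position`, `site`, configurable) among the immediately
  preceding tokens, and not when followed by a measurement unit — otherwise
  every `3.50 nM` would become a residue;
- Oliveira labels have no conventional surface form in running text, so the
  default grammar is cue-driven (a 3-digit integer after `Oliveira` or
  `GPCRDB number/position/residue`) and isolated behind configuration.

Ballesteros-Weinstein labels are `TM.n` with helix 1–8 and a two-digit
intra-helix index relative to the most conserved position (`.50`); parsing
and formatting are exact inverses on this label space, and strings with a
helix outside 1–8 (e.g. `9.50`) are rejected as plain decimals.

## Dictionaries and scoring

Three dictionaries are built from the knowledge base: gene identifiers,
protein identifiers (entry names and accessions) and protein descriptions;
manually curated synonyms are merged into the description dictionary, whose
tolerant scoring fits their free-text nature. Matching scans token windows
(never across sentence boundaries) and scores each (surface, key) pair as
`1 − d / max(|a|, |b|)`, where `d` is a weighted Damerau-Levenshtein distance
over canonicalized strings — case-folded, whitespace-collapsed, Greek
letters spelled out as Latin names (`β` → `beta`), with residual per-pair
substitution-cost overrides (hyphen ↔ space at cost 0 by default). Greek
expansion is a transliteration pass rather than a character-pair cost
because the equivalence is one-to-many.

Defaults: identifier classes accept 0.0 normalized distance (exact up to
case); descriptions accept 0.2. Both are configuration-overridable. These
thresholds are design choices, not measured constants. Punctuation inside
identifiers (`5-HT1A` vs `5HT1A`) is *not* normalized by default; the
hyphen/space override plus description-class tolerance absorbs most of this
in practice.

Overlap resolution prefers exact (score 1.0) hits over any overlapping
approximate hit, then longest span, then score: a fuzzy window that swallows
a neighbouring word ("… receptor in") must not shadow the clean match inside
it.

## Normalization

A protein mention is bound to a unique entry using species context. Only
candidates tied at the best match score compete (a 0.9 cross-family match
never blocks a 1.0 match from resolving). If the document mentions no
species, a unique candidate resolves by itself. Otherwise candidates are
filtered to species attested anywhere in the document — species scope is
document-wide, a deliberate choice surfaced in configuration — and the
species mention nearest to the protein mention (ties: nearest preceding,
then earliest) selects among them; if that still leaves more than one
candidate, or the filter empties the set, the mention stays unresolved with
its candidate list intact so the ambiguity can be reported downstream.

## Grounding and offset correction

Candidate proteins for a residue/mutation record are the document's
normalized protein mentions, ranked: same sentence first, then ascending
token distance, then nearest-preceding, then document order (the final
document-order tie-break is a convention, not an inferred rule). The best
candidate whose sequence *validates* the record wins; otherwise the
top-ranked candidate is emitted as `unvalidated`, and records with no
normalized protein at all are emitted with an empty protein — nothing is
silently dropped, so recall can be audited.

Validation routes:

- **direct** — the stated wild type matches the sequence at the stated
  position (`validated`);
- **offset-corrected** — one offset δ per (document, protein) is inferred
  jointly from all of that protein's sequential records that carry an amino
  acid: every δ in ±200 is scanned, the δ explaining the most records wins,
  ties go to the smallest |δ| and then to positive δ (the
  signal-peptide/longer-isoform direction). The window of 200 covers signal
  peptides and isoform N-terminal differences and is configurable. Once
  established, a non-zero offset is the article's numbering scheme: it is
  applied *before* trusting a coincidental direct hit at the uncorrected
  position, and retroactively to that protein's records lacking a stated
  amino acid. When all records fit at δ = 0 no offset is inferred.
- **generic-number lookup** — Ballesteros-Weinstein and Oliveira labels are
  inverted through the entry's numbering table; a stated amino acid must
  still agree with the sequence.

Every grounded annotation carries the knowledge-base sequential position,
the applied offset, both generic labels where the position is mapped
(structurally conserved positions only), the grounding distance in tokens
and a same-sentence flag. Records with an unknown amino acid and no
applicable offset cannot be sequence-checked and are reported `unvalidated`
rather than optimistically `validated`.

## Synthetic fixtures

The generator emulates the article/knowledge-base pairing the pipeline
consumes. Defaults define the study conditions: 3 proteins over 2 species
drawn from a fixed family pool (including deliberately shared descriptions
like "rhodopsin" to exercise ambiguity, and a Greek-letter description),
sequences of 300–400 random residues with a rejection step forbidding 8–10-mer
tandem repeats (so a planted offset is, with high probability, the unique
best explanation), generic-number labels on ~25% of positions across seven
helix segments, **4 mutation mentions per featured protein** — typical of
the handful of point mutants characterized per construct in GPCR mutagenesis
papers, and enough that a coincidental alternative offset (probability
≈ 400/20⁴ per document) is rare — drawn evenly from the six notation
families, and distractor sentences (decimal measurements, figure references,
`T4 lysozyme`, cell lines) at density 0.3. Everything is deterministic per
seed.

What the fixtures do **not** emulate: real article layout and length, OCR or
PDF-extraction noise, coreference ("the receptor", "this mutant"),
nucleotide-level variants, insertions/deletions, and the long-tail
morphology of real protein names. Passing on fixtures therefore demonstrates
the correctness of the documented rules, not corpus-level recall on real
literature. Gold grounding labels are only guaranteed when each mutation
sentence names its protein (the default); looser documents are checked
against an exhaustive brute-force ranker instead.

Scoring against gold is exact-span and exact-grounding; with zero
predictions of a type precision is reported as 1.0 (no prediction was
wrong), with zero gold annotations recall is 1.0.

## Problem sizes used in the automated checks

The test suite exercises offset recovery on 500 seeded single-protein
documents with offsets drawn uniformly in ±200, grounding-vs-oracle
equivalence on 200 seeded documents with 2–5 proteins and up to ~10 records,
score-vs-brute-force equality on a 50-name dictionary, and byte-level
determinism on 50 documents — sizes at which the exhaustive oracles remain
exact while covering the full rule chain.

## Known limitations

- Dictionary matching is window-based and exact-or-edit-bounded; heavily
  abbreviated or novel protein names outside the knowledge base are invisible
  by design (no machine-learned NER).
- One offset per (document, protein): articles that mix two numbering
  schemes for the same protein will validate only the majority scheme.
- The Oliveira surface grammar is a configurable guess; running text rarely
  spells these labels out.
- Two proteins tying exactly on every ranking criterion are broken by
  document order, which is arbitrary but deterministic.
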