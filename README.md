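# gpcranno

Text mining for the G protein-coupled receptor (GPCR) literature: find
species, protein, residue and point-mutation mentions in article text,
**normalize** protein mentions to knowledge-base identifiers, **ground**
residue and mutation mentions onto specific reference sequences (with
automatic correction of article-specific numbering offsets), and
interconvert the sequential, Ballesteros-Weinstein and Oliveira (GPCRDB)
residue numbering schemes.

It is aimed at curators and bioinformaticians who need machine-readable,
sequence-validated mutation annotations from GPCR papers — for example to
link a mutagenesis study from the pre-structure era to today's structural
knowledge — without any network services: the knowledge base is a local
directory of plain-text files.

## What it does

**Mention grammar.** Point mutations appear in many surface forms around the
`XnY` theme — wild-type residue X, sequence position n, substituted residue
Y. The grammar parses `D98F`, `Asp98Phe`, `Asp98 → Phe`, `Asp98-Phe98`,
`D98 to phenylalanine` and `Asp 98 was mutated to phenylalanine` to the same
canonical triple (D, 98, F). Residue mentions cover `Trp161`/`W161`/`Trp 161`,
bare Ballesteros-Weinstein labels such as `3.50` (helix 3, position 50
relative to the helix's most conserved residue), and cue-driven Oliveira
integer labels.

**Normalization.** Proteins are detected by approximate dictionary matching
over three dictionaries (gene identifiers, protein identifiers, free-text
descriptions), each with its own scoring: identifiers must match exactly up
to case, descriptions tolerate up to 20% weighted edits and treat Greek
letters and their Latin spellings as equivalent (β2-adrenergic ≡
beta2-adrenergic). A mention like "rhodopsin" stays ambiguous when the
knowledge base holds a rhodopsin for several species; "human rhodopsin"
resolves to `OPSD_HUMAN` via the species mentions in the document.

**Grounding.** Residue/mutation records are attached to the normalized
protein ranked best by a word-distance metric — same sentence first, then
token distance — and validated against that protein's sequence. When the
article numbers residues relative to a construct with a signal peptide or a
different isoform, a single per-document offset δ (article number − database
number) is inferred by scanning a ±200 window for the offset that explains
the most mentions, preferring the smallest |δ|. Grounded annotations carry
the sequential position plus both generic numbers where the position is
structurally conserved.

## Worked example

```python
from gpcranno import annotate_document
from gpcranno.fixtures import FixtureSpec, generate

res = generate(FixtureSpec(seed=3, planted_offset=24))   # synthetic article + KB
doc = res.documents[0]
aset = annotate_document(doc.text, res.kb, doc_id=doc.doc_id)
print(aset.stats)
for g in aset.grounded:
    print(g.record.span.text, "->", g.protein, g.sequential_position,
          g.applied_offset, g.validation.value, g.bw_label, g.oliveira_label)
```

prints

```
{'species': 6, 'proteins': 6, 'proteins_normalized': 6, 'mutations': 4,
 'residues': 1, 'grounded': 5, 'validated': 5}
Trp318 → Glu -> OPSD_BOVIN 294 24 corrected_by_offset None None
G259P        -> OPSD_BOVIN 235 24 corrected_by_offset None None
Met217 → Ser -> OPSD_BOVIN 193 24 corrected_by_offset None None
Trp156 → Tyr -> OPSD_BOVIN 132 24 corrected_by_offset None None
7.44         -> OPSD_BOVIN 316 0  general_number_lookup 7.44 178
```

The generator planted every mutation 24 positions above the database
numbering; the pipeline recovered the offset from the mentions alone, mapped
each mutation back to knowledge-base coordinates (e.g. article `Trp318` →
sequence position 294, where the sequence indeed carries tryptophan), and
resolved the bare generic label `7.44` through the numbering table.

The same pipeline is available from the shell:

```sh
gpcranno fixtures generate --out fx --seed 3 --n-documents 2
gpcranno kb validate --kb fx/kb
gpcranno annotate --kb fx/kb --in fx/docs/doc000.txt --out out --format json
gpcranno config show
```

Output is standoff annotation — character spans into the unmodified source
text — serialized as JSON (schema shipped with the package) or TSV.

## Knowledge-base layout

A knowledge-base directory holds four plain-text files: `proteins.fasta`
(reference sequences, record id = Swiss-Prot-style entry name),
`proteins.tsv` (accession, NCBI taxid, pipe-separated gene symbols,
descriptions and curated synonyms), `species.tsv` (taxid, pipe-separated
names) and `numbering.tsv` (entry name, sequential position,
Ballesteros-Weinstein label, Oliveira label; `-` for absent). `gpcranno
fixtures generate` emits a complete example.

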