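# ppzlink

Comparative conservation profiling of two phosphatase ortholog groups (PP1
vs PPZ) and BS3 chemical cross-link identification with contact mapping.

The package implements two analysis arms:

1. **Conservation arm** — per-column profiling of a joint PP1/PPZ multiple
   sequence alignment: conserved-position counting (with clade exclusion),
   difference-class assignment (A: conserved-but-different in both groups;
   B: constant in PP1, variable in PPZ; C: the symmetric case; D:
   clade-restricted differences), charge-category swap scanning
   (acidic/basic/neutral), motif-window identity/conservation reports,
   Shannon information-content logo matrices, pairwise identity summaries
   and a deterministic Saitou–Nei neighbor-joining phylogram (newick).
2. **Cross-link arm** — MGF ingestion, scan filtering (charge 3..9 plus
   tryptic-y1 and linker signature peaks), in-silico tryptic digestion
   (4 missed cleavages), BS3 cross-link / dead-end / linear candidate
   enumeration at 10 ppm, theoretical b/y fragments of cross-linked peptide
   pairs, fragment matching at 0.10 Da with the "ions from both peptides"
   approval rule, and a bidimensional contact map with region statistics.

Supporting modules: sequence I/O with full-length residue numbering
preserved through domain trimming (`seq_io`), residue-number transfer via
pairwise global alignment and motif scanning (`residue_map`), and
ground-truthed synthetic data generators for both arms (`synthetic_data`).

## Command line

```bash
# synthetic alignment with planted difference columns + truth table
ppzlink simulate-family --config family.yaml --out fam/ --seed 1

# conservation reports (classes, charge swaps, conserved counts, trees, ...)
ppzlink conservation --alignment fam/alignment.fasta --labels fam/labels.tsv --out cons/

# synthetic cross-link spectra + truth table
ppzlink simulate-xlms --config xlms.yaml --out sim/ --seed 1

# cross-link search (filter counts, candidates, approved links)
ppzlink xlms --mgf sim/spectra.mgf --fasta sim/proteins.fasta --out xl/

# bidimensional contact map from a cross-link table
# (rows: siteA <tab> partner list; "356/359" = ambiguous, "90, 113" = list)
ppzlink map --table links.tsv --config map.yaml --out map/
```

All reports are TSV with `#`-prefixed provenance headers; reruns with the
same inputs are byte-identical.

## Notes on conventions

* Residue numbering is 1-based, inclusive, and always in full-length
  coordinates; trimmed records carry an `offset` (e.g. a catalytic domain
  starting at residue 359 keeps positions 359..692).
* Chemistry constants (BS3 bridge C8H10O2, dead-ends C8H12O3/C8H13NO2,
  carbamidomethyl, oxidation) are derived from element masses and
  molecular formulas at import time, never hard-coded as decimals.
* Classification thresholds ("largely maintained" >= 0.90 dominant
  frequency, "substantial variation" < 0.70, charge-swap constancy >= 0.90)
  are configurable in `ConservationConfig`.
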