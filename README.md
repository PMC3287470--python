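# glylec

Toolkit for the bespoke computational stages of a C-type-lectin
characterization workflow: parsing linear glycan notations into
residue-level graphs, assembling them into isomeric SMILES for virtual
screening libraries, annotating lectin sequences with functional motifs
and N-glycosylation sequons under topological context rules, and
consensus-ranking docking poses re-scored by multiple scoring
functions.

## Who this is for

Glycobiologists and structural bioinformaticians who want to screen a
carbohydrate-binding protein (a C-type lectin with its Ca²⁺-dependent
carbohydrate recognition domain, or any sugar-binding receptor) against
a glycan-array-derived ligand library, and need the glue that commercial
docking suites do not provide: converting array notation into dockable
chemistry, reading motif-prediction output with biological context, and
stabilising multi-scoring-function output into one ranking.

## What it computes

**Glycan notation → graph → SMILES.** Condensed notation such as
`Galb1-4(Fuca1-3)GlcNAcb-Sp0` is parsed into a rooted tree of
monosaccharides (reducing end rightmost; branches parenthesised; array
spacers `-SpN` kept as metadata, not chemistry). Each residue is
instantiated from a stereochemically explicit pyranose template
(Glc, Gal, Man, GlcNAc, GalNAc, Fuc, Rha, Xyl, GlcA, Neu5Ac, Neu5Gc,
KDN; sulfate decorations via a `[6S]` prefix), and each glycosidic
linkage condenses the child's anomeric carbon onto a parent hydroxyl
with loss of one water:

```
formula(glycan) = Σ residue formulas − n_edges × H₂O
```

computed twice by independent code paths (elemental arithmetic vs. the
assembled atom graph) as a built-in conservation check. A numeric
tuple-per-residue dialect is supported alongside the condensed text.

**Motif scanning.** A restricted PROSITE-style grammar (literals,
`[ST]` classes, `{^P}` negation, `x` wildcard) over the protein
alphabet, with a shipped catalog: `EPN` (mannose-type sugar
specificity), `WND` (Ca²⁺ coordination), `YxxL` (hemi-ITAM),
`[ST]xx[DE]` (casein kinase II), `[PSAT]x[QE]E` (TRAF2 binding), and
the sequon `N{^P}[ST]`. All overlapping matches are reported with
1-based coordinates. Hits are filtered against a membrane topology
annotation — a cytoplasmic-context motif found in the ectodomain of a
type-II transmembrane receptor is a false positive and is discarded
with the rule that fired — and multi-predictor feature tables can be
reduced to ≥ *k*-way consensus.

**Consensus screening.** Docking poses re-scored by a panel of
functions (LigScore1/2 and Jain higher-better; PLP1/2 and PMF
lower-better) are reduced to per-ligand best scores per site, ranked
per function (competition ranking, ties share the better rank), and
combined by rank-by-vote: a ligand earns a vote from each function
placing it in the top `⌈q·U⌉` of `U` unique ligands; ligands are ordered
by votes, then mean rank, then id, and the top `⌈f·U⌉` are selected
(defaults q = f = 0.25). Selected sets are profiled by terminal
monosaccharide: for each terminal sugar (with anomer), the proportion
of library glycans carrying it that were selected.

## Worked example

```python
>>> from glylec import parse_condensed, emit_smiles, terminal_residues, build_library
>>> g = parse_condensed("Neu5Aca2-3Galb1-4Glcb")     # 3'-sialyllactose
>>> a = emit_smiles(g)
>>> a.formula_string
'C23H39NO19'
>>> sorted(f"{r.symbol}({r.anomer})" for r in terminal_residues(g))
['Neu5Ac(alpha)']
>>> m = build_library(["Man", "Galb1-4(Fuca1-3)GlcNAcb-Sp0", "Xxxb1-4Glc"])
>>> m.n_converted, m.n_total, m.coverage_percent
(2, 3, 66.7)
>>> m.failed()[0].failure_reason
'unknown-residue'
```

The formula `C23H39NO19` is the exact condensation arithmetic
(C11H19NO9 + 2 × C6H12O6 − 2 H₂O); the emitted SMILES carries full ring
stereochemistry and parses in any cheminformatics toolkit. The library
report says two of three lines converted (66.7% coverage) and why the
third did not.

The same operations are available from the shell:

```
glylec glycan library --in glycans.txt --out lib/ --format smiles
glylec motifs scan --fasta lectin.fasta --topology topo.tsv --out hits.tsv
glylec screen consensus --poses poses.tsv --q 0.25 --top 0.25 --out screen/
glylec screen profile --selected screen/selected.tsv --manifest lib/manifest.json --out profile.tsv
```

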