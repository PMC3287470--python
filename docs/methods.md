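# Methods

## Scope

The toolkit implements the computation that sits *between* standard
resources in a lectin characterization workflow: array notation →
dockable ligand chemistry, predictor output → context-filtered feature
calls, and multi-function pose scores → a consensus ranking and a
terminal-sugar binding profile. It deliberately does not predict
domains or topology (Pfam/SMART/TMHMM-class tools do that), build
homology models, detect cavities, dock, or implement any scoring
function: those stages are consumed as inputs (FASTA, feature/topology
TSVs, pose-score TSVs) or delegated to external tools (the conformer
hook).

## Glycan notation

The condensed dialect follows glycan-array print conventions: the
rightmost residue is the reducing end and tree root; each unit is
`Symbol` + anomer (`a`/`b`/`?`) + linkage `c-p` (child anomeric carbon,
parent position); parenthesised segments attach to the residue
immediately to their right; a trailing `-SpN` spacer is array
chemistry, stripped from the molecule and retained as metadata; a
bracketed prefix (`[6S]`) carries substituents. Sialic acids link
through C2; all other registered residues through C1. Serialization is
canonical: children are ordered by descending parent position, the
highest-position child continues the backbone and the remaining
branches are parenthesised, which makes parse∘serialize the identity
up to child-order normalisation.

The numeric dialect (tuples of residue code, anomer code, parent
position, parent index) is this package's own documented stand-in for
array-database numeric encodings, whose exact specification is not
public. Its contract is equivalence with the condensed dialect
(`parse_glycodigit(encode_glycodigit(g)) == g`), not byte-compatibility
with any external system.

Internally residues are 0-indexed; every user-facing coordinate
(diagnostics, motif hits, profiles) is 1-based.

## Monosaccharide templates and stereochemistry

Hexopyranoses are generated from a Haworth up/down table anchored on
D-glucopyranose in the standard 4C1 depiction (anomeric oxygen down for
α, up for β; C5 hydroxymethyl up for the D series). Galactose and
mannose are the C4 and C2 epimers; the 2-acetamido sugars keep the
orientation of the hydroxyl they replace; xylose drops C6; glucuronic
acid oxidises it. L-sugars (fucose = 6-deoxy-galactose, rhamnose =
6-deoxy-mannose) are built as the mirror image of the corresponding
D-template, which also mirrors the anomeric reference, so α-L comes out
correct by construction. Sialic acids (Neu5Ac, Neu5Gc, KDN) use the
D-glycero-D-galacto nonulosonate ring, anomeric centre C2 bearing the
carboxyl, glycerol tail at C6–C9. Tetrahedral parities were fixed once
against textbook CIP descriptors (β-D-glucopyranose 2R,3R,4S,5S,6R on
oxane numbering; the standard α-Neu5Ac reference structure) and are
frozen constants; the suite independently re-checks emitted
stereochemistry through an external toolkit's sanitizer.

Available linkage positions per residue are the free ring hydroxyls
(e.g. {2,3,4,6} for Glc, {3,4,6} for GlcNAc since C2 carries the
acetamido group, {2,3,4} for the 6-deoxy sugars, {4,7,8,9} for sialic
acids). Attempting to link through an absent hydroxyl is a validation
error, not a silently wrong molecule; the same holds for unsupported
decorations (only O-sulfation is implemented; any other substituent
code fails the entry).

## Assembly conventions

One water is eliminated per glycosidic edge. The bridging oxygen is
contributed by the parent hydroxyl and the child loses its anomeric OH
— chemically equivalent to the opposite convention, fixed for
determinism. The reducing end keeps a free anomeric hydroxyl in its
stated configuration; an unspecified anomer is emitted as α and the
molecule flagged (`root-anomer-unspecified`), since a screen should
know it received a convention rather than a measurement. Emission is a
pure function: depth-first from the root with children in canonical
order, so equal graphs give byte-identical SMILES. No canonical-SMILES
algorithm is promised — cross-implementation string equality is
explicitly not a contract; formula and graph invariants are.

Two independent code paths guard mass balance: `molecular_formula`
(template sums minus edge waters, never touching atoms) and the
assembled atom graph's element tally. Ring integrity holds because each
template contributes exactly one ring and bridges add none
(cycle rank = residue count).

## Library builds

Batch conversion is per-entry fault-isolated: every line is parsed,
validated and emitted independently, failures recorded with the
diagnostic code that fired. Coverage = converted / total, reported to
one decimal in percent, the precision used in array-conversion reports.
Identifiers default to 1-based line numbers (array lists are
positional) unless an `id<TAB>notation` prefix is given. Terminal
residues are the tree leaves with their anomers; a single-residue
glycan terminates with itself so monosaccharide controls enter
terminal-profile denominators. The conformer hook shells out to an
external generator per entry (`{input}`/`{output}` SDF template),
counts `$$$$` records, and degrades to a warning no-op when
unconfigured or the tool is absent — the package itself computes no 3-D
coordinates.

## Motif scanning and context filtering

Patterns compile to per-position allowed-residue sets; scanning is an
O(L·W) sliding window reporting *all* overlapping matches (biological
sites overlap; greedy consumption would hide them). A motif's
"position" is the 1-based index of its first matched residue. The
sequon finder is the same engine applied to `N{^P}[ST]`.

The shipped catalog covers the motifs whose patterns are printed and
unambiguous (EPN, WND, YxxL, CKII `[ST]xx[DE]`, TRAF2 `[PSAT]x[QE]E`,
and the sequon). Kinase and adaptor patterns that are only defined
server-side (PKC, GSK3, CtBP) are intentionally not guessed; users add
them through the catalog TSV.

Context filtering encodes the transmembrane-receptor plausibility rule:
each motif declares a required compartment (cytoplasmic /
extracellular / transmembrane / any), and a hit survives only if its
full span lies inside one topology segment of that kind — a hit
straddling a boundary is rejected too. Rejections carry the rule that
fired, so filtered output is auditable. Predictor consensus keeps
features reported by ≥ k predictors at the same start (exact by
default; an optional ±w window clusters greedily by ascending start);
the result is monotone: raising k can only shrink it.

## Consensus screening

The literature around the LigScore/PLP/Jain/PMF panel does not pin down
one "consensus score"; this package fixes the standard rank-by-vote
formulation and documents it: per site and function, ligands are ranked
on their best pose (orientation-aware; competition ranking so ties
share the better rank); a ligand earns one vote per function ranking it
within the top ⌈q·U⌉; ordering is votes desc, mean rank asc, ligand id
asc; the top ⌈f·U⌉ unique ligands are selected. Defaults q = f = 0.25
("top 25% unique ligands"); ceiling selection guarantees a non-empty
result for any U ≥ 1. Missing scores yield no vote and are excluded
from the mean rank rather than erroring, matching how partial re-scoring
output arrives in practice. Orientations default to LigScore1/2 and
Jain higher-better, PLP1/2 and PMF lower-better, overridable by config.

The terminal profile divides, per terminal monosaccharide (symbol +
anomer), the selected glycans carrying it by the converted library
glycans carrying it; multi-terminal glycans count in every applicable
terminal and empty denominators are omitted.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (params, seed) via named
substreams of a counter-based RNG; no global state.

*Glycan sampler*: grows a random tree over the registered residues,
attaching each new residue to a free template position (tip-extension
vs. branching controlled by `branch_probability`; defaults: ≤ 8
residues, 0.25 branching, 0.3 spacer, 0.05 sulfation — magnitudes
typical of mammalian array glycans). Strings are produced by
serialising the graph, so samples are grammar-valid with ground truth
by construction. The sampler does **not** reproduce real array
composition statistics (core structures, biosynthetic constraints),
so passing conversion tests shows the machinery is sound, not that any
particular published array converts at a particular rate.

*Score tables*: planted winners receive an orientation-correct boost of
1 + 4·noise_scale over N(0, noise_scale²) backgrounds, best pose first.
Noiseless recovery is therefore exact by construction and noisy
recovery demonstrates margin-over-noise behaviour — not the accuracy of
any docking program.

*Benchmark receptor*: a 378-residue type-II membrane protein
(cytoplasmic 1–90, transmembrane 91–113, extracellular 114–378) with
features planted at the canonical report positions for this receptor
class — hemi-ITAM at 7, CKII at 16/42/68, TRAF2 at 30, a mislocated
cytoplasmic-context decoy at 121 in the ectodomain, sequons at 215 and
237, EPN at 341 and WND at 359. The background alphabet excludes every
residue the shipped patterns require, so a scan recovers exactly the
planted layout; this makes the regression deterministic but means the
benchmark says nothing about motif statistics on natural sequence
composition. It is a synthetic stand-in, not a UniProt record: scanning
a real lectin requires the user's own FASTA (and topology prediction),
for which the CLI is the intended path.

## Numerical and degenerate-input choices

Ties in consensus ranking fall back to ligand id for full determinism.
`q`, `f` outside (0, 1] and empty inputs raise; per-entry failures
never abort a batch. Unspecified linkage positions are resolved to the
lowest free acceptor position and flagged. Formula comparisons are
exact integer arithmetic; no floating-point tolerances exist anywhere
in the chemistry. Topology annotations must tile 1..L exactly; gaps and
overlaps are errors rather than warnings because every downstream
filter depends on coverage.

## Known limitations

Furanoses, repeating units, undetermined-topology glycans,
glycopeptides and non-sulfate substituents are out of scope. The
emitted SMILES is isomeric but not canonical. The α/β convention for
free sialic-acid reducing ends follows the common α reference
structure. Homology-model quality statistics (sequence identity,
Ramachandran proportions, cavity counts) and per-terminal docking
proportions from the original screening context depend on commercial
modeling and docking software plus unpublished pose scores, and are
not reproduced here; the property suites in `tests/` are the
verification surface instead.
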