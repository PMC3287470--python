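"""Glycan graph -> isomeric SMILES assembly.

Every glycosidic edge condenses the child's anomeric carbon onto a
parent hydroxyl with loss of one water; by convention the bridging
oxygen is the parent's (the child loses its anomeric OH), which is
chemically equivalent either way but keeps the emitter deterministic.
The reducing-end residue keeps a free anomeric hydroxyl in its stated
configuration; unspecified anomers are built as alpha and flagged, so a
downstream screen can treat such entries with caution rather than
silently receiving an arbitrary stereoisomer.

``molecular_formula`` deliberately never touches atom graphs: it sums
residue template formulas and subtracts one water per edge, so it can
serve as an independent conservation check on ``emit_smiles``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._chem import Molecule, formula_to_string
from .graph import UNSPECIFIED, Diagnostic, GlycanGraph, NotationError
from .notation import validate_graph
from .residues import get_template, residue_formula

_WATER = Counter({"H": 2, "O": 1})


class AssemblyError(ValueError):
    """Graph failed validation or an edge cannot be realised chemically."""

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(str(d) for d in diagnostics))

    @property
    def code(self) -> str:
        return self.diagnostics[0].code if self.diagnostics else "unknown"


@dataclass
class AssembledMolecule:
    """SMILES plus bookkeeping for one converted glycan."""

    smiles: str
    formula: Counter
    #: per-residue atom index ranges [start, end) in construction order
    residue_atom_spans: list[tuple[int, int]]
    flags: list[str] = field(default_factory=list)
    molecule: Molecule | None = None

    @property
    def formula_string(self) -> str:
        return formula_to_string(self.formula)


def molecular_formula(graph: GlycanGraph) -> Counter:
    """Elemental formula by residue-sum minus one water per linkage.

    Computed without building the molecule; the independent path for
    conservation checks against :func:`emit_smiles`.
    """
    total: Counter = Counter()
    for r in graph.residues:
        total += residue_formula(r)
    total -= Counter({k: v * len(graph.edges) for k, v in _WATER.items()})
    return +total


def emit_smiles(graph: GlycanGraph) -> AssembledMolecule:
    """Build one connected molecule from a validated glycan graph.

    Pure function: equal graphs give byte-identical SMILES (depth-first
    from the reducing end, children in canonical order).
    """
    errors = [d for d in validate_graph(graph) if d.severity == "error"]
    if errors:
        raise AssemblyError(errors)

    mol = Molecule()
    flags: list[str] = []
    spans: dict[int, tuple[int, int]] = {}

    def build(i: int, exit_oxygen: int | None) -> None:
        ref = graph.residues[i]
        tmpl = get_template(ref.symbol)
        start = len(mol)
        inst = tmpl.instantiate(mol, ref, exit_oxygen=exit_oxygen)
        spans[i] = (start, len(mol))
        if ref.anomer == UNSPECIFIED:
            flags.append(
                "root-anomer-unspecified" if i == graph.root_index else f"anomer-unspecified:residue-{i + 1}"
            )
        free = {p for p in inst.oxygens if p != tmpl.anomeric_position}
        for child, link in graph.children(i):
            pos = link.parent_position
            if pos is None:
                if not free:
                    raise AssemblyError(
                        [Diagnostic("error", "no-free-position", f"residue {i + 1} has no free hydroxyl left")]
                    )
                pos = min(free)
                flags.append(f"parent-position-unspecified:residue-{child + 1}->assigned-{pos}")
            if pos not in free:
                raise AssemblyError(
                    [Diagnostic("error", "invalid-position", f"residue {i + 1}: position {pos} unavailable")]
                )
            free.discard(pos)
            bridge = inst.oxygens[pos]
            # condensation: the parent hydroxyl loses its hydrogen and
            # becomes the glycosidic bridge; the child is built without
            # its anomeric hydroxyl (one water per edge in total)
            mol.atoms[bridge].hcount = 0
            build(child, exit_oxygen=bridge)

    build(graph.root_index, None)
    smiles = mol.to_smiles(0)
    return AssembledMolecule(
        smiles=smiles,
        formula=mol.formula(),
        residue_atom_spans=[spans[i] for i in sorted(spans)],
        flags=flags,
        molecule=mol,
    )


# ---------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------

def smiles_record(identifier: str, assembled: AssembledMolecule) -> str:
    """One ``SMILES<TAB>identifier`` line."""
    return f"{assembled.smiles}\t{identifier}"


def sdf_record(
    identifier: str,
    assembled: AssembledMolecule,
    source_text: str | None = None,
) -> str:
    """A V2000 molfile record (all-zero 2-D coordinates) with data fields.

    Stereochemistry is carried by the SMILES output, not by the flat
    SDF; the SDF exists as a container for identifiers and as input to
    external conformer generators.
    """
    mol = assembled.molecule
    if mol is None:
        raise ValueError("assembled molecule graph not retained")
    bonds = []
    for i in range(len(mol)):
        for j, order in mol.neighbors(i):
            if j > i:
                bonds.append((i, j, order))
    lines = [identifier, "  glylec 2D", ""]
    lines.append(f"{len(mol):>3}{len(bonds):>3}  0  0  0  0  0  0  0  0999 V2000")
    for atom in mol.atoms:
        lines.append(f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {atom.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in bonds:
        lines.append(f"{i + 1:>3}{j + 1:>3}{order:>3}  0  0  0  0")
    lines.append("M  END")
    lines.append("> <id>")
    lines.append(identifier)
    lines.append("")
    if source_text is not None:
        lines.append("> <source_notation>")
        lines.append(source_text)
        lines.append("")
    lines.append("$$$$")
    return "\n".join(lines)
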