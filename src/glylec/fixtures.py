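"""Seeded synthetic inputs with known ground truth.

Every generator is a pure function of its parameters and a single
integer seed (each generator derives its own named substream, so the
glycan, score-table and sequence corpora are independent).  The
generators exist so the whole toolkit is testable without any
downloads: glycan strings come with their ground-truth graphs, score
tables with their planted winners, sequences with their planted motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import ALPHA, BETA, UNSPECIFIED, GlycanGraph, GlycosidicLinkage, MonosaccharideRef
from .motifs import (
    AMINO_ACIDS,
    MotifDefinition,
    MotifHit,
    TopologyAnnotation,
    TopologySegment,
    compile_motif,
)
from .notation import serialize_condensed
from .residues import REGISTRY, get_template
from .consensus import ScoringFunctionSpec, default_functions

_STREAM_GLYCANS = 11
_STREAM_SCORES = 22
_STREAM_SEQUENCES = 33


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


# ---------------------------------------------------------------------
# glycan grammar sampler
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class GrammarParams:
    max_residues: int = 8
    branch_probability: float = 0.25
    residue_alphabet: tuple[str, ...] = tuple(REGISTRY)
    spacer_probability: float = 0.3
    substituent_probability: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_residues < 1:
            raise ValueError("max_residues must be >= 1")
        for p in (self.branch_probability, self.spacer_probability, self.substituent_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.residue_alphabet:
            raise ValueError("residue alphabet must be non-empty")
        unknown = [s for s in self.residue_alphabet if s not in REGISTRY]
        if unknown:
            raise ValueError(f"unregistered residues in alphabet: {unknown}")


def random_glycan(params: GrammarParams, rng: np.random.Generator | None = None) -> tuple[str, GlycanGraph]:
    """One random grammar-valid glycan: (notation string, ground-truth graph).

    The string is produced by serialising the graph, so the pair is
    consistent by construction; with ``branch_probability`` 0 the tree
    is a linear chain.
    """
    if rng is None:
        rng = _rng(params.seed, _STREAM_GLYCANS)
    n = int(rng.integers(1, params.max_residues + 1))

    residues: list[MonosaccharideRef] = []
    edges: list[tuple[int, int, GlycosidicLinkage]] = []
    free: dict[int, set[int]] = {}

    def new_residue(is_root: bool) -> int:
        symbol = str(rng.choice(params.residue_alphabet))
        tmpl = get_template(symbol)
        if is_root:
            anomer = [ALPHA, BETA, UNSPECIFIED][int(rng.choice(3, p=[0.45, 0.45, 0.1]))]
        else:
            anomer = ALPHA if rng.random() < 0.5 else BETA
        positions = set(tmpl.acceptor_positions)
        subs: tuple[str, ...] = ()
        if positions and rng.random() < params.substituent_probability:
            pos = int(rng.choice(sorted(positions)))
            subs = (f"{pos}S",)
            positions.discard(pos)
        residues.append(MonosaccharideRef(symbol, anomer, substituents=subs))
        idx = len(residues) - 1
        free[idx] = positions
        return idx

    tip = new_residue(is_root=True)
    for _ in range(n - 1):
        candidates = [i for i in free if free[i]]
        if not candidates:
            break
        if free.get(tip) and (len(candidates) == 1 or rng.random() >= params.branch_probability):
            parent = tip
        else:
            others = [c for c in candidates if c != tip] or candidates
            parent = int(others[int(rng.integers(len(others)))])
        child = new_residue(is_root=False)
        pos = int(rng.choice(sorted(free[parent])))
        free[parent].discard(pos)
        edges.append((parent, child, GlycosidicLinkage(get_template(residues[child].symbol).anomeric_position, pos)))
        tip = child

    spacer = None
    if rng.random() < params.spacer_probability:
        spacer = f"Sp{int(rng.integers(0, 26))}"
    graph = GlycanGraph(residues=residues, edges=edges, root_index=0, spacer=spacer)
    text = serialize_condensed(graph)
    graph.source_text = text
    return text, graph


def random_glycan_corpus(n: int, params: GrammarParams) -> list[tuple[str, GlycanGraph]]:
    """``n`` independent samples from one seeded stream."""
    rng = _rng(params.seed, _STREAM_GLYCANS)
    return [random_glycan(params, rng) for _ in range(n)]


# ---------------------------------------------------------------------
# synthetic docking-score tables
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreTableParams:
    n_ligands: int = 20
    n_sites: int = 2
    n_functions: int = 6
    poses_per_ligand: int = 3
    planted_top: int = 5
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ligands, self.n_sites, self.n_functions, self.poses_per_ligand) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.planted_top <= self.n_ligands:
            raise ValueError("planted_top must lie in [0, n_ligands]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.n_functions > len(default_functions()):
            raise ValueError("n_functions exceeds the registered panel")


def synthetic_score_table(params: ScoreTableParams) -> tuple[str, frozenset[str], list[ScoringFunctionSpec]]:
    """A poses TSV with a planted superior ligand set.

    Planted ligands receive an orientation-correct boost of
    ``1 + 4 * noise_scale`` on every function (so the margin always
    exceeds the noise scale); pose 1 carries each ligand's intended
    value, later poses are strictly worse.  Returns (tsv text, planted
    ligand ids, function specs); byte-identical for equal parameters.
    """
    rng = _rng(params.seed, _STREAM_SCORES)
    functions = default_functions()[: params.n_functions]
    width = max(3, len(str(params.n_ligands)))
    ligands = [f"L{i + 1:0{width}d}" for i in range(params.n_ligands)]
    planted = frozenset(
        str(x) for x in rng.choice(ligands, size=params.planted_top, replace=False)
    )
    boost = 1.0 + 4.0 * params.noise_scale
    header = "\t".join(["ligand_id", "site_id", "pose_id"] + [f.name for f in functions])
    rows = [header]
    for s in range(params.n_sites):
        site = f"site{s + 1}"
        for lig in ligands:
            base = boost if lig in planted else 0.0
            targets = {}
            for f in functions:
                noise = params.noise_scale * rng.normal()
                targets[f.name] = (base + noise) if f.orientation == "higher_better" else (-base + noise)
            for p in range(params.poses_per_ligand):
                cells = [lig, site, f"pose{p + 1}"]
                for f in functions:
                    worse = 0.0 if p == 0 else (p + rng.random()) * 0.1
                    v = targets[f.name] - worse if f.orientation == "higher_better" else targets[f.name] + worse
                    cells.append(f"{v:.6f}")
                rows.append("\t".join(cells))
    return "\n".join(rows) + "\n", planted, functions


# ---------------------------------------------------------------------
# planted motif sequences
# ---------------------------------------------------------------------

def planted_motif_sequence(
    length: int,
    plants: list[tuple[MotifDefinition | str, int]],
    seed: int = 0,
    background: str | None = None,
) -> tuple[str, list[MotifHit]]:
    """A random protein sequence with motif instances written at given
    1-based positions.

    Background residues are drawn uniformly from ``background`` (default
    the 20-letter alphabet), so *accidental* matches elsewhere are
    possible and expected: ground truth is planted hits plus whatever a
    scan finds.  Overlapping plants are allowed only where they agree on
    the shared residues.
    """
    rng = _rng(seed, _STREAM_SEQUENCES)
    alphabet = sorted(background or AMINO_ACIDS)
    seq: list[str | None] = [None] * length
    truth: list[MotifHit] = []
    for pat, pos in plants:
        motif = compile_motif(pat, pat) if isinstance(pat, str) else pat
        if pos < 1 or pos + motif.width - 1 > length:
            raise ValueError(f"plant {motif.id!r} at {pos} exceeds sequence length {length}")
        chars = []
        for k, allowed in enumerate(motif.positions):
            cell = pos - 1 + k
            if seq[cell] is not None:
                if seq[cell] not in allowed:
                    raise ValueError(f"conflicting plants at position {cell + 1}")
                chars.append(seq[cell])
                continue
            choice = str(rng.choice(sorted(allowed)))
            seq[cell] = choice
            chars.append(choice)
        truth.append(MotifHit(motif.id, pos, pos + motif.width - 1, "".join(chars)))
    for i in range(length):
        if seq[i] is None:
            seq[i] = str(alphabet[int(rng.integers(len(alphabet)))])
    return "".join(seq), truth


# ---------------------------------------------------------------------
# synthetic type-II lectin benchmark sequence
# ---------------------------------------------------------------------

#: background alphabet that cannot create any shipped motif by chance
#: (no S/T/N/Y/E/Q/D/P), so every catalog hit on the synthetic receptor
#: is a planted one
_INERT_BACKGROUND = "ACFGHIKLMRVW"


@dataclass(frozen=True)
class SyntheticLectin:
    """A synthetic stand-in for a type-II transmembrane C-type lectin.

    This is generated data, not a real protein: a 378-residue sequence
    with a cytoplasmic tail (1-90), one transmembrane helix (91-113) and
    an extracellular region (114-378), carrying a hemi-ITAM, CKII sites,
    a TRAF2 motif, one deliberately mislocated cytoplasmic-context
    motif in the ectodomain (a false positive for the context filter),
    two N-glycosylation sequons and the EPN/WND sugar-binding pair at
    the canonical report positions.
    """

    sequence_id: str
    sequence: str
    topology: TopologyAnnotation
    planted: dict[str, tuple[int, ...]] = field(default_factory=dict)


def synthetic_clec17a(seed: int = 0) -> SyntheticLectin:
    """Deterministic synthetic benchmark receptor.

    Planted features (1-based starts): hemi-ITAM 7; CKII 16, 42, 68
    (cytoplasmic) and 121 (extracellular decoy); TRAF2 30; sequons 215
    and 237; EPN 341; WND 359.  The background alphabet contains none
    of the residues any shipped pattern requires, so a catalog scan
    returns exactly the planted hits.
    """
    planted = {
        "hemi-ITAM": (7,),
        "CKII": (16, 42, 68, 121),
        "TRAF2": (30,),
        "N-glyc-sequon": (215, 237),
        "EPN": (341,),
        "WND": (359,),
    }
    plants: list[tuple[str, int]] = []
    plants += [("YxxL", 7)]
    plants += [("[ST]xx[DE]", p) for p in planted["CKII"]]
    plants += [("[PSAT]x[QE]E", 30)]
    plants += [("N{P}[ST]", p) for p in planted["N-glyc-sequon"]]
    plants += [("EPN", 341), ("WND", 359)]
    # wildcard positions inside plants must stay inert too, so plant
    # against the restricted alphabet by intersecting class choices
    restricted = [
        (compile_motif(f"plant{k}", pat), pos) if isinstance(pat, str) else (pat, pos)
        for k, (pat, pos) in enumerate(plants)
    ]
    narrowed = []
    inert = frozenset(_INERT_BACKGROUND)
    for motif, pos in restricted:
        positions = tuple(
            (allowed & inert) if (allowed & inert) else allowed for allowed in motif.positions
        )
        narrowed.append(
            (
                MotifDefinition(
                    id=motif.id,
                    pattern=motif.pattern,
                    category=motif.category,
                    required_context=motif.required_context,
                    source=motif.source,
                    positions=positions,
                ),
                pos,
            )
        )
    sequence, _ = planted_motif_sequence(378, narrowed, seed=seed, background=_INERT_BACKGROUND)
    topology = TopologyAnnotation(
        (
            TopologySegment("inside", 1, 90),
            TopologySegment("transmembrane", 91, 113),
            TopologySegment("outside", 114, 378),
        )
    )
    return SyntheticLectin("SYNLEC1", sequence, topology, planted)
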