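"""Monosaccharide templates: ring chemistry, stereochemistry, linkable positions.

Each registered residue carries a recipe that instantiates its pyranose
ring into a molecular graph.  Hexopyranoses are generated from a Haworth
up/down table anchored on D-glucopyranose (4C1 chair conventions):

* D-series templates place the C5 hydroxymethyl "up"; alpha puts the
  anomeric oxygen "down", beta "up".
* Gal is the C4 epimer and Man the C2 epimer of Glc; the 2-acetamido
  sugars keep the orientation of the hydroxyl they replace.
* L-sugars (Fuc = 6-deoxy-Gal, Rha = 6-deoxy-Man) are built as the
  mirror image of the corresponding D-template, which also flips the
  anomeric reference, so "alpha-L" comes out correctly by construction.

Sialic acids (Neu5Ac, Neu5Gc, KDN) use the D-glycero-D-galacto
nonulosonate ring with the anomeric centre at C2 and the exocyclic
glycerol tail at C6-C9.

Stereo parities below were fixed once by checking the emitted
monosaccharides against their textbook CIP descriptors (e.g.
beta-D-glucopyranose = 2R,3R,4S,5S,6R on oxane numbering).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._chem import H_IMPLICIT, Molecule
from .graph import ALPHA, BETA, UNSPECIFIED, MonosaccharideRef

# Calibrated: for a ring carbon written with stereo neighbours ordered
# [previous ring atom, next ring atom, up substituent, down substituent]
# (ring listed anomeric-first, Haworth viewed from above, clockwise),
# this parity reproduces the textbook configurations.
_HAWORTH_PARITY = "@"


def _haworth(mol: Molecule, atom: int, prev: int, nxt: int, up: int, down: int) -> None:
    mol.set_stereo(atom, [prev, nxt, up, down], _HAWORTH_PARITY)


@dataclass
class ResidueInstance:
    """One residue instantiated inside a molecule under assembly."""

    anomeric_carbon: int
    #: free hydroxyl oxygens by carbon position (acceptors for children,
    #: plus the anomeric position when the residue is a root)
    oxygens: dict[int, int]
    atoms: list[int]


@dataclass(frozen=True)
class MonosaccharideTemplate:
    """Chemical template of one registered residue."""

    symbol: str
    ring_form: str
    anomeric_position: int  # 1 for aldoses, 2 for sialic acids
    acceptor_positions: frozenset[int]  # hydroxyl positions children may occupy
    formula: Counter  # free monosaccharide, Hill elements
    _kind: str  # "hexose" | "sialic"
    _params: tuple

    def instantiate(
        self,
        mol: Molecule,
        ref: MonosaccharideRef,
        exit_oxygen: int | None = None,
    ) -> ResidueInstance:
        """Append this residue's atoms to ``mol``.

        ``exit_oxygen`` is the parent's bridging oxygen when the residue
        is a child; when ``None`` a free anomeric hydroxyl is created
        (reducing end).  Unspecified anomers are built as alpha — the
        caller is responsible for flagging them.
        """
        anomer = ALPHA if ref.anomer == UNSPECIFIED else ref.anomer
        if self._kind == "hexose":
            inst = _instantiate_hexose(mol, anomer, exit_oxygen, *self._params)
        else:
            inst = _instantiate_sialic(mol, anomer, exit_oxygen, *self._params)
        _apply_substituents(mol, inst, ref, self)
        return inst


_SULFATE_FORMULA = Counter({"S": 1, "O": 3})


def _apply_substituents(
    mol: Molecule,
    inst: ResidueInstance,
    ref: MonosaccharideRef,
    template: MonosaccharideTemplate,
) -> None:
    for token in ref.substituents:
        pos, code = parse_substituent(token)
        if code != "S":
            raise UnsupportedSubstituentError(ref.symbol, token)
        oxy = inst.oxygens.get(pos)
        if oxy is None:
            raise UnsupportedSubstituentError(ref.symbol, token)
        # O-sulfation: -O-H becomes -O-S(=O)(=O)-OH
        mol.atoms[oxy].hcount = 0
        s = mol.add_atom("S")
        o1 = mol.add_atom("O")
        o2 = mol.add_atom("O")
        o3 = mol.add_atom("O", hcount=1)
        mol.add_bond(oxy, s)
        mol.add_bond(s, o1, order=2)
        mol.add_bond(s, o2, order=2)
        mol.add_bond(s, o3)
        inst.atoms.extend([s, o1, o2, o3])
        del inst.oxygens[pos]


class UnsupportedSubstituentError(ValueError):
    def __init__(self, symbol: str, token: str):
        self.symbol = symbol
        self.token = token
        super().__init__(f"unsupported substituent {token!r} on {symbol}")


def parse_substituent(token: str) -> tuple[int, str]:
    """Split a decoration token like '6S' into (position, code)."""
    i = 0
    while i < len(token) and token[i].isdigit():
        i += 1
    if i == 0 or i == len(token):
        raise ValueError(f"malformed substituent token {token!r}")
    return int(token[:i]), token[i:]


# ---------------------------------------------------------------------
# hexopyranose construction
# ---------------------------------------------------------------------

def _flip(o: str) -> str:
    return "d" if o == "u" else "u"


def _instantiate_hexose(
    mol: Molecule,
    anomer: str,
    exit_oxygen: int | None,
    orient: tuple[str, str, str],  # Haworth up/down of O2, O3, O4 (D-series)
    c6: str | None,  # "CH2OH" | "CH3" | "COOH" | None (pentose)
    c2_n: str | None,  # None | "Ac" | None — N-acyl replaces O2
    mirror: bool,  # L-series: mirror every centre
) -> ResidueInstance:
    o2o, o3o, o4o = orient
    anomer_o = "u" if anomer == BETA else "d"
    c6o = "u"
    if mirror:
        o2o, o3o, o4o, anomer_o, c6o = map(_flip, (o2o, o3o, o4o, anomer_o, c6o))

    c1 = mol.add_atom("C", hcount=1)
    c2 = mol.add_atom("C", hcount=1)
    c3 = mol.add_atom("C", hcount=1)
    c4 = mol.add_atom("C", hcount=1)
    c5 = mol.add_atom("C", hcount=1 if c6 is not None else 2)
    o5 = mol.add_atom("O")
    ring = [c1, c2, c3, c4, c5, o5]
    atoms = list(ring)
    for a, b in zip(ring, ring[1:] + ring[:1]):
        mol.add_bond(a, b)

    oxygens: dict[int, int] = {}

    # anomeric centre
    if exit_oxygen is None:
        exit_oxygen = mol.add_atom("O", hcount=1)
        atoms.append(exit_oxygen)
        oxygens[1] = exit_oxygen
    mol.add_bond(c1, exit_oxygen)
    up, down = (exit_oxygen, H_IMPLICIT) if anomer_o == "u" else (H_IMPLICIT, exit_oxygen)
    _haworth(mol, c1, o5, c2, up, down)

    # C2: hydroxyl or N-acyl
    if c2_n is None:
        o2 = mol.add_atom("O", hcount=1)
        atoms.append(o2)
        mol.add_bond(c2, o2)
        oxygens[2] = o2
        sub2 = o2
    else:
        n = mol.add_atom("N", hcount=1)
        cc = mol.add_atom("C")
        oo = mol.add_atom("O")
        cm = mol.add_atom("C", hcount=3)
        mol.add_bond(c2, n)
        mol.add_bond(n, cc)
        mol.add_bond(cc, oo, order=2)
        mol.add_bond(cc, cm)
        atoms.extend([n, cc, oo, cm])
        sub2 = n
    up, down = (sub2, H_IMPLICIT) if o2o == "u" else (H_IMPLICIT, sub2)
    _haworth(mol, c2, c1, c3, up, down)

    for c, prev, nxt, oo in ((c3, c2, c4, o3o), (c4, c3, c5, o4o)):
        o = mol.add_atom("O", hcount=1)
        atoms.append(o)
        mol.add_bond(c, o)
        oxygens[3 if c == c3 else 4] = o
        up, down = (o, H_IMPLICIT) if oo == "u" else (H_IMPLICIT, o)
        _haworth(mol, c, prev, nxt, up, down)

    # C5 exocyclic group
    if c6 is not None:
        if c6 == "CH2OH":
            x = mol.add_atom("C", hcount=2)
            o6 = mol.add_atom("O", hcount=1)
            mol.add_bond(x, o6)
            atoms.extend([x, o6])
            oxygens[6] = o6
        elif c6 == "CH3":
            x = mol.add_atom("C", hcount=3)
            atoms.append(x)
        elif c6 == "COOH":
            x = mol.add_atom("C")
            od = mol.add_atom("O")
            oh = mol.add_atom("O", hcount=1)
            mol.add_bond(x, od, order=2)
            mol.add_bond(x, oh)
            atoms.extend([x, od, oh])
        else:  # pragma: no cover - table is closed
            raise ValueError(c6)
        mol.add_bond(c5, x)
        up, down = (x, H_IMPLICIT) if c6o == "u" else (H_IMPLICIT, x)
        _haworth(mol, c5, c4, o5, up, down)

    return ResidueInstance(anomeric_carbon=c1, oxygens=oxygens, atoms=atoms)


# ---------------------------------------------------------------------
# sialic-acid (nonulosonate) construction
# ---------------------------------------------------------------------

# (O4 up?, C5-substituent up?, C7-tail up?, C7 parity, C8 parity,
#  alpha anomer exit-oxygen up?) — frozen after calibration against the
# alpha-Neu5Ac reference structure.
_SIALIC_FLAGS = (False, True, False, "@@", "@@", False)

def _instantiate_sialic(
    mol: Molecule,
    anomer: str,
    exit_oxygen: int | None,
    c5_group: str,  # "NAc" | "NGc" | "OH"
) -> ResidueInstance:
    # Haworth orientations of the D-glycero-D-galacto ring, calibrated
    # against the standard alpha-Neu5Ac isomeric SMILES (ring CIP
    # 2R,4S,5R,6R for the alpha anomer, glycerol tail R,R).
    o4_up, o5_up, o6_up, p7, p8, alpha_exit_up = _SIALIC_FLAGS
    exit_up = alpha_exit_up if anomer == ALPHA else not alpha_exit_up

    c2 = mol.add_atom("C")  # anomeric, no H
    c3 = mol.add_atom("C", hcount=2)
    c4 = mol.add_atom("C", hcount=1)
    c5 = mol.add_atom("C", hcount=1)
    c6 = mol.add_atom("C", hcount=1)
    o6 = mol.add_atom("O")
    ring = [c2, c3, c4, c5, c6, o6]
    atoms = list(ring)
    for a, b in zip(ring, ring[1:] + ring[:1]):
        mol.add_bond(a, b)

    oxygens: dict[int, int] = {}

    # C1 carboxyl on the anomeric carbon
    c1 = mol.add_atom("C")
    od = mol.add_atom("O")
    oh = mol.add_atom("O", hcount=1)
    mol.add_bond(c1, od, order=2)
    mol.add_bond(c1, oh)
    mol.add_bond(c2, c1)
    atoms.extend([c1, od, oh])

    if exit_oxygen is None:
        exit_oxygen = mol.add_atom("O", hcount=1)
        atoms.append(exit_oxygen)
        oxygens[2] = exit_oxygen
    mol.add_bond(c2, exit_oxygen)
    up, down = (exit_oxygen, c1) if exit_up else (c1, exit_oxygen)
    _haworth(mol, c2, o6, c3, up, down)

    # C4 hydroxyl
    o4 = mol.add_atom("O", hcount=1)
    mol.add_bond(c4, o4)
    atoms.append(o4)
    oxygens[4] = o4
    up, down = (o4, H_IMPLICIT) if o4_up else (H_IMPLICIT, o4)
    _haworth(mol, c4, c3, c5, up, down)

    # C5 substituent
    if c5_group == "OH":
        o5x = mol.add_atom("O", hcount=1)
        mol.add_bond(c5, o5x)
        atoms.append(o5x)
        oxygens[5] = o5x
        sub5 = o5x
    else:
        n = mol.add_atom("N", hcount=1)
        cc = mol.add_atom("C")
        oo = mol.add_atom("O")
        mol.add_bond(c5, n)
        mol.add_bond(n, cc)
        mol.add_bond(cc, oo, order=2)
        atoms.extend([n, cc, oo])
        if c5_group == "NAc":
            cm = mol.add_atom("C", hcount=3)
            mol.add_bond(cc, cm)
            atoms.append(cm)
        else:  # NGc: glycolyl CH2OH
            cm = mol.add_atom("C", hcount=2)
            og = mol.add_atom("O", hcount=1)
            mol.add_bond(cc, cm)
            mol.add_bond(cm, og)
            atoms.extend([cm, og])
        sub5 = n
    up, down = (sub5, H_IMPLICIT) if o5_up else (H_IMPLICIT, sub5)
    _haworth(mol, c5, c4, c6, up, down)

    # C6 carries the glycerol tail
    c7 = mol.add_atom("C", hcount=1)
    mol.add_bond(c6, c7)
    up, down = (c7, H_IMPLICIT) if o6_up else (H_IMPLICIT, c7)
    _haworth(mol, c6, c5, o6, up, down)

    o7 = mol.add_atom("O", hcount=1)
    c8 = mol.add_atom("C", hcount=1)
    mol.add_bond(c7, o7)
    mol.add_bond(c7, c8)
    o8 = mol.add_atom("O", hcount=1)
    c9 = mol.add_atom("C", hcount=2)
    mol.add_bond(c8, o8)
    mol.add_bond(c8, c9)
    o9 = mol.add_atom("O", hcount=1)
    mol.add_bond(c9, o9)
    atoms.extend([c7, o7, c8, o8, c9, o9])
    oxygens.update({7: o7, 8: o8, 9: o9})

    # glycerol tail stereo (D-glycero)
    mol.set_stereo(c7, [c6, c8, o7, H_IMPLICIT], p7)
    mol.set_stereo(c8, [c7, c9, o8, H_IMPLICIT], p8)

    return ResidueInstance(anomeric_carbon=c2, oxygens=oxygens, atoms=atoms)


# ---------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------

_HEXOSE = Counter({"C": 6, "H": 12, "O": 6})
_DEOXYHEXOSE = Counter({"C": 6, "H": 12, "O": 5})
_PENTOSE = Counter({"C": 5, "H": 10, "O": 5})
_HEXNAC = Counter({"C": 8, "H": 15, "N": 1, "O": 6})
_HEXA = Counter({"C": 6, "H": 10, "O": 7})

_GLC = ("d", "u", "d")
_MAN = ("u", "u", "d")
_GAL = ("d", "u", "u")


def _hexose_template(symbol, formula, orient, c6, c2_n, mirror, acceptors):
    return MonosaccharideTemplate(
        symbol=symbol,
        ring_form="pyranose",
        anomeric_position=1,
        acceptor_positions=frozenset(acceptors),
        formula=formula,
        _kind="hexose",
        _params=(orient, c6, c2_n, mirror),
    )


def _sialic_template(symbol, formula, c5_group, acceptors):
    return MonosaccharideTemplate(
        symbol=symbol,
        ring_form="pyranose",
        anomeric_position=2,
        acceptor_positions=frozenset(acceptors),
        formula=formula,
        _kind="sialic",
        _params=(c5_group,),
    )


REGISTRY: dict[str, MonosaccharideTemplate] = {
    "Glc": _hexose_template("Glc", _HEXOSE, _GLC, "CH2OH", None, False, {2, 3, 4, 6}),
    "Gal": _hexose_template("Gal", _HEXOSE, _GAL, "CH2OH", None, False, {2, 3, 4, 6}),
    "Man": _hexose_template("Man", _HEXOSE, _MAN, "CH2OH", None, False, {2, 3, 4, 6}),
    "GlcNAc": _hexose_template("GlcNAc", _HEXNAC, _GLC, "CH2OH", "Ac", False, {3, 4, 6}),
    "GalNAc": _hexose_template("GalNAc", _HEXNAC, _GAL, "CH2OH", "Ac", False, {3, 4, 6}),
    "Fuc": _hexose_template("Fuc", _DEOXYHEXOSE, _GAL, "CH3", None, True, {2, 3, 4}),
    "Rha": _hexose_template("Rha", _DEOXYHEXOSE, _MAN, "CH3", None, True, {2, 3, 4}),
    "Xyl": _hexose_template("Xyl", _PENTOSE, _GLC, None, None, False, {2, 3, 4}),
    "GlcA": _hexose_template("GlcA", _HEXA, _GLC, "COOH", None, False, {2, 3, 4}),
    "Neu5Ac": _sialic_template("Neu5Ac", Counter({"C": 11, "H": 19, "N": 1, "O": 9}), "NAc", {4, 7, 8, 9}),
    "Neu5Gc": _sialic_template("Neu5Gc", Counter({"C": 11, "H": 19, "N": 1, "O": 10}), "NGc", {4, 7, 8, 9}),
    "KDN": _sialic_template("KDN", Counter({"C": 9, "H": 16, "O": 9}), "OH", {4, 5, 7, 8, 9}),
}

#: residue tokens, longest first, for the tokenizer
SYMBOLS_BY_LENGTH: list[str] = sorted(REGISTRY, key=len, reverse=True)


class UnknownResidueError(KeyError):
    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unknown residue symbol {symbol!r}")


def get_template(ref: MonosaccharideRef | str) -> MonosaccharideTemplate:
    """Template for a residue reference (or bare symbol)."""
    symbol = ref if isinstance(ref, str) else ref.symbol
    try:
        return REGISTRY[symbol]
    except KeyError:
        raise UnknownResidueError(symbol) from None


def residue_formula(ref: MonosaccharideRef) -> Counter:
    """Free-monosaccharide formula including substituent contributions."""
    f = Counter(get_template(ref).formula)
    for token in ref.substituents:
        _, code = parse_substituent(token)
        if code == "S":
            f += _SULFATE_FORMULA
        else:
            raise UnsupportedSubstituentError(ref.symbol, token)
    return f
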