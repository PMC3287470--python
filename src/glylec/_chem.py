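"""Minimal molecular graph with a stereochemistry-aware SMILES writer.

The assembler composes monosaccharide rings into one molecule, so all we
need is: atoms with explicit hydrogen counts, single/double bonds,
tetrahedral centres stored as a reference neighbour ordering plus a
parity, elemental formulas, and deterministic SMILES emission.  This is
deliberately not a general cheminformatics kit — no aromaticity, no
charges beyond what sugars need, no perception of anything.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

#: sentinel standing for the implicit hydrogen in a stereo neighbour list
H_IMPLICIT = -1

_ORGANIC_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}


@dataclass(eq=False)
class Atom:
    element: str
    hcount: int = 0
    charge: int = 0
    #: reference neighbour ordering (atom indices; H_IMPLICIT allowed once)
    stereo_order: list[int] | None = None
    #: '@' means: looking from the first reference neighbour, the
    #: remaining three appear anticlockwise
    stereo_parity: str | None = None


class Molecule:
    """Mutable molecular graph; indices are stable (no deletion)."""

    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self._adj: dict[int, list[tuple[int, int]]] = {}

    # -- construction -------------------------------------------------
    def add_atom(self, element: str, hcount: int = 0, charge: int = 0) -> int:
        self.atoms.append(Atom(element, hcount, charge))
        idx = len(self.atoms) - 1
        self._adj[idx] = []
        return idx

    def add_bond(self, i: int, j: int, order: int = 1) -> None:
        if i == j:
            raise ValueError("self bond")
        if any(n == j for n, _ in self._adj[i]):
            raise ValueError(f"duplicate bond {i}-{j}")
        self._adj[i].append((j, order))
        self._adj[j].append((i, order))

    def set_stereo(self, i: int, order: list[int], parity: str) -> None:
        if parity not in ("@", "@@"):
            raise ValueError("parity must be '@' or '@@'")
        real = [n for n in order if n != H_IMPLICIT]
        bonded = {n for n, _ in self._adj[i]}
        if set(real) != bonded or len(order) != len(bonded) + order.count(H_IMPLICIT):
            raise ValueError(f"stereo order of atom {i} does not match its bonds")
        if order.count(H_IMPLICIT) != (1 if self.atoms[i].hcount == 1 else 0):
            raise ValueError("implicit-H sentinel inconsistent with hcount")
        self.atoms[i].stereo_order = list(order)
        self.atoms[i].stereo_parity = parity

    def neighbors(self, i: int) -> list[tuple[int, int]]:
        return list(self._adj[i])

    # -- properties ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def formula(self) -> Counter:
        counts: Counter = Counter()
        for a in self.atoms:
            counts[a.element] += 1
            counts["H"] += a.hcount
        return +counts

    def n_bonds(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    def n_components(self) -> int:
        seen: set[int] = set()
        comps = 0
        for start in range(len(self.atoms)):
            if start in seen:
                continue
            comps += 1
            stack = [start]
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                stack.extend(n for n, _ in self._adj[u] if n not in seen)
        return comps

    def ring_count(self) -> int:
        """Cycle rank: independent rings in the graph."""
        return self.n_bonds() - len(self.atoms) + self.n_components()

    # -- SMILES emission ----------------------------------------------
    def to_smiles(self, root: int = 0) -> str:
        """Deterministic SMILES, depth-first from ``root``.

        Children are visited in bond-insertion order, so equal
        construction sequences yield byte-identical strings.
        """
        parent: dict[int, int | None] = {root: None}
        order: list[int] = []
        visited: set[int] = set()
        ring_bonds: list[tuple[int, int]] = []
        stack: list[int] = [root]
        while stack:
            u = stack.pop()
            if u in visited:
                continue
            visited.add(u)
            order.append(u)
            children = []
            for v, _ in self._adj[u]:
                if v == parent.get(u):
                    continue
                if v in visited:
                    key = (min(u, v), max(u, v))
                    if key not in ring_bonds:
                        ring_bonds.append(key)
                elif v not in parent:
                    parent[v] = u
                    children.append(v)
            # LIFO stack: push reversed so insertion order is preserved
            stack.extend(reversed(children))
        if len(visited) != len(self.atoms):
            raise ValueError("disconnected molecule cannot be written as one SMILES")

        pos = {a: k for k, a in enumerate(order)}
        # ring-closure digit assignment: digit opened at the earlier atom
        digits: dict[int, list[tuple[int, int, int]]] = {i: [] for i in range(len(self.atoms))}
        for num, (i, j) in enumerate(
            sorted(ring_bonds, key=lambda b: (min(pos[b[0]], pos[b[1]]), max(pos[b[0]], pos[b[1]]))),
            start=1,
        ):
            a, b = (i, j) if pos[i] < pos[j] else (j, i)
            digits[a].append((num, b, self._bond_order(a, b)))
            digits[b].append((num, a, self._bond_order(a, b)))

        out: list[str] = []
        self._write_atom(root, None, parent, digits, out)
        return "".join(out)

    def _bond_order(self, i: int, j: int) -> int:
        for n, o in self._adj[i]:
            if n == j:
                return o
        raise KeyError((i, j))

    def _children(self, u: int, parent: dict[int, int | None]) -> list[int]:
        return [v for v, _ in self._adj[u] if parent.get(v) == u and v != parent.get(u)]

    def _write_atom(
        self,
        u: int,
        prev: int | None,
        parent: dict[int, int | None],
        digits: dict[int, list[tuple[int, int, int]]],
        out: list[str],
    ) -> None:
        atom = self.atoms[u]
        ring_here = sorted(digits[u])
        children = self._children(u, parent)

        # written neighbour order: previous atom, implicit H, ring
        # closures in digit order, then children in written order
        written: list[int] = []
        if prev is not None:
            written.append(prev)
        if atom.hcount == 1 and atom.stereo_order is not None:
            written.append(H_IMPLICIT)
        written.extend(partner for _, partner, _ in ring_here)
        written.extend(children)

        out.append(self._atom_token(u, written))
        for num, _, bond_order in ring_here:
            if bond_order == 2:
                out.append("=")
            out.append(str(num) if num < 10 else f"%{num}")
        for k, child in enumerate(children):
            last = k == len(children) - 1
            if not last:
                out.append("(")
            if self._bond_order(u, child) == 2:
                out.append("=")
            self._write_atom(child, u, parent, digits, out)
            if not last:
                out.append(")")

    def _atom_token(self, u: int, written: list[int]) -> str:
        atom = self.atoms[u]
        if atom.stereo_order is not None:
            sym = atom.stereo_parity
            if _permutation_parity(atom.stereo_order, written):
                sym = "@@" if sym == "@" else "@"
            h = "H" if atom.hcount == 1 else (f"H{atom.hcount}" if atom.hcount else "")
            chg = "" if not atom.charge else ("+" if atom.charge == 1 else "-" if atom.charge == -1 else f"{atom.charge:+d}")
            return f"[{atom.element}{sym}{h}{chg}]"
        if atom.charge == 0 and atom.element in _ORGANIC_VALENCE:
            implied = _ORGANIC_VALENCE[atom.element] - sum(o for _, o in self._adj[u])
            if implied == atom.hcount:
                return atom.element
        h = "" if atom.hcount == 0 else ("H" if atom.hcount == 1 else f"H{atom.hcount}")
        chg = "" if not atom.charge else ("+" if atom.charge == 1 else "-" if atom.charge == -1 else f"{atom.charge:+d}")
        return f"[{atom.element}{h}{chg}]"


def _permutation_parity(ref: list[int], written: list[int]) -> bool:
    """True if ``written`` is an odd permutation of ``ref``."""
    if sorted(ref) != sorted(written):
        raise ValueError(f"neighbour sets differ: {ref} vs {written}")
    perm = [ref.index(x) for x in written]
    swaps = 0
    perm = list(perm)
    for i in range(len(perm)):
        while perm[i] != i:
            j = perm[i]
            perm[i], perm[j] = perm[j], perm[i]
            swaps += 1
    return swaps % 2 == 1


def formula_to_string(counts: Counter) -> str:
    """Hill-order formula string (C, H, then alphabetical)."""
    parts: list[str] = []
    for el in ["C", "H"] + sorted(k for k in counts if k not in ("C", "H")):
        n = counts.get(el, 0)
        if n == 0:
            continue
        parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)
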