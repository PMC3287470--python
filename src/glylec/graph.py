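"""Residue-level glycan graphs.

A glycan is a rooted tree of monosaccharide residues joined by
glycosidic linkages.  The root is the reducing end (rightmost residue
in condensed notation); leaves are the non-reducing terminal residues
that lectins typically read.  Indices are 0-based internally; every
user-facing report converts to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

ALPHA = "alpha"
BETA = "beta"
UNSPECIFIED = "unspecified"

_ANOMER_CHARS = {"a": ALPHA, "b": BETA, "?": UNSPECIFIED}
_ANOMER_TO_CHAR = {ALPHA: "a", BETA: "b", UNSPECIFIED: "?"}


def anomer_from_char(c: str) -> str:
    try:
        return _ANOMER_CHARS[c]
    except KeyError:
        raise ValueError(f"unknown anomer character {c!r}") from None


def anomer_to_char(a: str) -> str:
    return _ANOMER_TO_CHAR[a]


@dataclass(frozen=True)
class MonosaccharideRef:
    """A residue occurrence: symbol + anomeric configuration.

    ``substituents`` holds decoration tokens such as ``"6S"`` (sulfate
    on O6); ``ring_form`` is pyranose for every residue in the shipped
    table (furanoses are parsed only if a template ever registers one).
    """

    symbol: str
    anomer: str = UNSPECIFIED
    ring_form: str = "pyranose"
    substituents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.anomer not in (ALPHA, BETA, UNSPECIFIED):
            raise ValueError(f"bad anomer {self.anomer!r}")
        if self.ring_form not in ("pyranose", "furanose"):
            raise ValueError(f"bad ring form {self.ring_form!r}")


@dataclass(frozen=True)
class GlycosidicLinkage:
    """child anomeric carbon -> parent hydroxyl position.

    ``parent_position`` is ``None`` when the notation leaves the
    attachment position unspecified (e.g. ``a1-?``).
    """

    child_position: int
    parent_position: int | None

    def __str__(self) -> str:
        p = "?" if self.parent_position is None else str(self.parent_position)
        return f"{self.child_position}-{p}"


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    code: str
    message: str
    span: tuple[int, int] | None = None  # [start, end) character offsets

    def __str__(self) -> str:
        loc = "" if self.span is None else f" @ {self.span[0]}..{self.span[1]}"
        return f"{self.severity}[{self.code}]{loc}: {self.message}"


@dataclass
class GlycanGraph:
    """Rooted, ordered tree of residues.

    ``edges`` are (parent_index, child_index, linkage) triples.  Two
    graphs compare equal when their rooted trees match after child-order
    normalisation; ``source_text`` is provenance and ignored by ``==``.
    """

    residues: list[MonosaccharideRef]
    edges: list[tuple[int, int, GlycosidicLinkage]]
    root_index: int = 0
    spacer: str | None = None
    source_text: str | None = None

    # -- topology helpers --------------------------------------------
    def children(self, i: int) -> list[tuple[int, GlycosidicLinkage]]:
        """Children of residue ``i``, parent_position ascending, unspecified last."""
        out = [(c, l) for p, c, l in self.edges if p == i]
        out.sort(key=lambda cl: (cl[1].parent_position is None, cl[1].parent_position or 0, cl[0]))
        return out

    def parent(self, i: int) -> tuple[int, GlycosidicLinkage] | None:
        for p, c, l in self.edges:
            if c == i:
                return p, l
        return None

    def leaves(self) -> list[int]:
        """Terminal (non-reducing end) residues; the root counts if alone."""
        with_children = {p for p, _, _ in self.edges}
        return [i for i in range(len(self.residues)) if i not in with_children]

    def is_tree(self) -> bool:
        n = len(self.residues)
        if len(self.edges) != n - 1:
            return False
        seen = {self.root_index}
        stack = [self.root_index]
        while stack:
            u = stack.pop()
            for c, _ in self.children(u):
                if c in seen:
                    return False
                seen.add(c)
                stack.append(c)
        return len(seen) == n

    # -- equality up to child-order normalisation --------------------
    def _key(self, i: int) -> tuple:
        kids = sorted(
            (
                (l.parent_position is None, l.parent_position or 0, l.child_position, self._key(c))
                for c, l in self.children(i)
            )
        )
        r = self.residues[i]
        return (r.symbol, r.anomer, r.ring_form, r.substituents, tuple(kids))

    def canonical_key(self) -> tuple:
        return (self._key(self.root_index), self.spacer)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanGraph):
            return NotImplemented
        return self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash(self.canonical_key())


def single_residue_graph(ref: MonosaccharideRef, source_text: str | None = None) -> GlycanGraph:
    return GlycanGraph(residues=[ref], edges=[], root_index=0, source_text=source_text)


class NotationError(ValueError):
    """Raised when a notation string cannot be parsed into a graph."""

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(str(d) for d in diagnostics) or "notation error")

    @property
    def code(self) -> str:
        return self.diagnostics[0].code if self.diagnostics else "unknown"
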