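"""Parsing and serialization of linear glycan notations.

Two dialects are supported:

* **Condensed IUPAC** as printed on glycan-array lists:
  ``Galb1-4(Fuca1-3)GlcNAcb-Sp0``.  The rightmost residue is the
  reducing end (root); ``a``/``b``/``?`` give the anomer; ``1-4`` pairs
  are child-anomeric-carbon/parent-position; parenthesised segments are
  branches attached to the residue immediately to their right; a
  trailing ``-SpN`` token is array spacer chemistry, stripped from the
  molecule and kept as metadata; a ``[6S]`` prefix carries substituents
  (sulfate) of the following residue.

* **A numeric "glycodigit-style" dialect** defined by this package (the
  encoding cited alongside condensed IUPAC in the source array lists is
  not publicly specified, so this dialect is a documented stand-in and
  makes no byte-compatibility claim).  A glycan is ``;``-separated
  residue tuples in the same left-to-right order as the condensed text,
  each tuple ``residue_code.anomer_code.parent_position.parent_index``
  with an optional fifth field of ``+``-joined substituent tokens.
  Codes: residues are numbered from 1 in registry order
  (Glc=1, Gal=2, Man=3, GlcNAc=4, GalNAc=5, Fuc=6, Rha=7, Xyl=8,
  GlcA=9, Neu5Ac=10, Neu5Gc=11, KDN=12); anomer 0=unspecified,
  1=alpha, 2=beta; ``parent_index`` is 1-based into the tuple list with
  0 marking the root; ``parent_position`` 0 means unspecified.  An
  optional trailing ``|SpN`` records the spacer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .graph import (
    ALPHA,
    BETA,
    UNSPECIFIED,
    Diagnostic,
    GlycanGraph,
    GlycosidicLinkage,
    MonosaccharideRef,
    NotationError,
    anomer_from_char,
    anomer_to_char,
)
from .residues import REGISTRY, SYMBOLS_BY_LENGTH, get_template, parse_substituent

_SPACER_RE = re.compile(r"-(Sp\d+)\s*$")

_RESIDUE_CODES: dict[str, int] = {sym: i for i, sym in enumerate(REGISTRY, start=1)}
_CODE_RESIDUES: dict[int, str] = {v: k for k, v in _RESIDUE_CODES.items()}
_ANOMER_CODES = {UNSPECIFIED: 0, ALPHA: 1, BETA: 2}
_CODE_ANOMERS = {v: k for k, v in _ANOMER_CODES.items()}


# ---------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class _Tok:
    kind: str  # "residue" | "open" | "close"
    span: tuple[int, int]
    symbol: str = ""
    anomer: str = UNSPECIFIED
    linkage: GlycosidicLinkage | None = None
    substituents: tuple[str, ...] = ()


def _err(code: str, message: str, span: tuple[int, int] | None = None) -> NotationError:
    return NotationError([Diagnostic("error", code, message, span)])


def _tokenize(text: str) -> list[_Tok]:
    toks: list[_Tok] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c == "(":
            toks.append(_Tok("open", (i, i + 1)))
            i += 1
            continue
        if c == ")":
            toks.append(_Tok("close", (i, i + 1)))
            i += 1
            continue
        start = i
        subs: tuple[str, ...] = ()
        if c == "[":
            end = text.find("]", i)
            if end < 0:
                raise _err("unbalanced-brackets", "substituent group '[' never closed", (i, n))
            raw = text[i + 1 : end]
            try:
                for t in raw.split(","):
                    parse_substituent(t.strip())
                subs = tuple(t.strip() for t in raw.split(","))
            except ValueError:
                raise _err("malformed-substituent", f"bad substituent group {raw!r}", (i, end + 1)) from None
            i = end + 1
            if i >= n:
                raise _err("malformed-substituent", "substituent group with no residue", (start, n))
        sym = None
        for cand in SYMBOLS_BY_LENGTH:
            if text.startswith(cand, i):
                sym = cand
                break
        if sym is None:
            m = re.match(r"[A-Za-z0-9]+", text[i:])
            bad = m.group(0) if m else text[i]
            raise _err("unknown-residue", f"unknown residue token {bad!r}", (i, i + len(bad)))
        i += len(sym)
        anomer = UNSPECIFIED
        if i < n and text[i] in "ab?":
            anomer = anomer_from_char(text[i])
            i += 1
        linkage = None
        if i < n and text[i].isdigit():
            m = re.match(r"(\d)-(\d|\?)", text[i:])
            if not m:
                frag = text[i : min(n, i + 3)]
                raise _err("malformed-linkage", f"malformed linkage {frag!r}", (i, min(n, i + 3)))
            child_pos = int(m.group(1))
            parent_pos = None if m.group(2) == "?" else int(m.group(2))
            linkage = GlycosidicLinkage(child_pos, parent_pos)
            i += m.end()
        toks.append(_Tok("residue", (start, i), sym, anomer, linkage, subs))
    return toks


# ---------------------------------------------------------------------
# condensed IUPAC
# ---------------------------------------------------------------------

def parse_condensed(text: str) -> GlycanGraph:
    """Parse a condensed-IUPAC string into a :class:`GlycanGraph`.

    Raises :class:`~glylec.graph.NotationError` on malformed input; the
    exception carries :class:`~glylec.graph.Diagnostic` records with
    character spans into ``text``.
    """
    source = text
    stripped = text.strip()
    if not stripped:
        raise _err("empty-input", "empty notation string")
    spacer = None
    m = _SPACER_RE.search(stripped)
    if m:
        spacer = m.group(1)
        stripped = stripped[: m.start()]
    toks = _tokenize(stripped)
    if not toks:
        raise _err("empty-input", "no residues found")

    residues: list[MonosaccharideRef] = []
    edges: list[tuple[int, int, GlycosidicLinkage]] = []

    def new_residue(tok: _Tok) -> int:
        residues.append(
            MonosaccharideRef(tok.symbol, tok.anomer, substituents=tok.substituents)
        )
        return len(residues) - 1

    def parse_chain(pos: int, depth: int) -> tuple[int, int]:
        """Parse tokens from ``pos``; returns (root_or_tail_index, next_pos).

        At depth 0 consumes to the end and returns the reducing-end
        root.  At depth > 0 stops at the matching ')' and returns the
        branch tail (which must carry a linkage).
        """
        pending: list[tuple[int, GlycosidicLinkage]] = []
        while pos < len(toks):
            tok = toks[pos]
            if tok.kind == "open":
                tail, pos = parse_chain(pos + 1, depth + 1)
                if pos >= len(toks) or toks[pos].kind != "close":
                    raise _err("unbalanced-parentheses", "branch never closed", tok.span)
                pos += 1
                link = _branch_link[tail]
                pending.append((tail, link))
                continue
            if tok.kind == "close":
                if depth == 0:
                    raise _err("unbalanced-parentheses", "unmatched ')'", tok.span)
                if len(pending) != 1:
                    raise _err("malformed-branch", "branch must end in a linked residue", tok.span)
                return pending[0][0], pos
            # residue token
            idx = new_residue(tok)
            for child, link in pending:
                edges.append((idx, child, link))
            pending = []
            if tok.linkage is not None:
                _branch_link[idx] = tok.linkage
                pending = [(idx, tok.linkage)]
                pos += 1
                continue
            # no linkage: must be the reducing end at depth 0, final token
            if depth > 0:
                raise _err("missing-linkage", f"branch residue {tok.symbol!r} lacks a linkage", tok.span)
            if pos + 1 != len(toks):
                raise _err("missing-linkage", f"residue {tok.symbol!r} lacks a linkage", tok.span)
            return idx, pos + 1
        if depth > 0:
            raise _err("unbalanced-parentheses", "branch never closed", toks[-1].span)
        if len(pending) == 1:
            # string ended on a linked residue, e.g. "Mana1-2"
            raise _err(
                "missing-root", "notation ends with a dangling linkage", toks[-1].span
            )
        raise _err("missing-root", "no reducing-end residue found", toks[-1].span)

    _branch_link: dict[int, GlycosidicLinkage] = {}
    root, _ = parse_chain(0, 0)
    return GlycanGraph(residues=residues, edges=edges, root_index=root, spacer=spacer, source_text=source)


def serialize_condensed(graph: GlycanGraph) -> str:
    """Canonical condensed-IUPAC text for a graph.

    Children are ordered by descending parent position (unspecified
    last); the first-listed (highest-position) child is the
    unparenthesised backbone continuation, remaining branches are
    parenthesised.  ``parse_condensed`` of the output reproduces the
    graph up to child-order normalisation.
    """

    def residue_text(i: int, is_root: bool) -> str:
        r = graph.residues[i]
        subs = f"[{','.join(r.substituents)}]" if r.substituents else ""
        if is_root:
            a = "" if r.anomer == UNSPECIFIED else anomer_to_char(r.anomer)
            return f"{subs}{r.symbol}{a}"
        return f"{subs}{r.symbol}{anomer_to_char(r.anomer)}"

    def ser(i: int, is_root: bool, link: GlycosidicLinkage | None) -> str:
        kids = graph.children(i)
        kids.sort(key=lambda cl: (cl[1].parent_position is None, -(cl[1].parent_position or 0), cl[0]))
        parts: list[str] = []
        for k, (child, clink) in enumerate(kids):
            chunk = ser(child, False, clink)
            parts.append(chunk if k == 0 else f"({chunk})")
        me = residue_text(i, is_root)
        if not is_root and link is not None:
            p = "?" if link.parent_position is None else str(link.parent_position)
            me = f"{me}{link.child_position}-{p}"
        return "".join(parts) + me

    out = ser(graph.root_index, True, None)
    if graph.spacer:
        out += f"-{graph.spacer}"
    return out


# ---------------------------------------------------------------------
# numeric dialect
# ---------------------------------------------------------------------

def parse_glycodigit(code: str) -> GlycanGraph:
    """Parse the numeric dialect documented in the module docstring."""
    text = code.strip()
    if not text:
        raise _err("empty-input", "empty code")
    spacer = None
    if "|" in text:
        text, _, sp = text.partition("|")
        sp = sp.strip()
        if not re.fullmatch(r"Sp\d+", sp):
            raise _err("malformed-spacer", f"bad spacer field {sp!r}")
        spacer = sp
    tuples = [t.strip() for t in text.split(";") if t.strip()]
    if not tuples:
        raise _err("empty-input", "no residue tuples")
    residues: list[MonosaccharideRef] = []
    parents: list[tuple[int, int]] = []  # (parent_index 1-based, parent_position)
    for k, tup in enumerate(tuples):
        fields = tup.split(".")
        if len(fields) not in (4, 5):
            raise _err("malformed-tuple", f"tuple {tup!r} must have 4 or 5 fields")
        try:
            rcode, acode, ppos, pidx = (int(f) for f in fields[:4])
        except ValueError:
            raise _err("malformed-tuple", f"non-numeric field in tuple {tup!r}") from None
        if rcode not in _CODE_RESIDUES:
            raise _err("unknown-residue-code", f"unknown residue code {rcode} in tuple {k + 1}")
        if acode not in _CODE_ANOMERS:
            raise _err("unknown-anomer-code", f"unknown anomer code {acode} in tuple {k + 1}")
        subs: tuple[str, ...] = ()
        if len(fields) == 5 and fields[4]:
            try:
                for t in fields[4].split("+"):
                    parse_substituent(t)
                subs = tuple(fields[4].split("+"))
            except ValueError:
                raise _err("malformed-substituent", f"bad substituent field in tuple {k + 1}") from None
        residues.append(MonosaccharideRef(_CODE_RESIDUES[rcode], _CODE_ANOMERS[acode], substituents=subs))
        parents.append((pidx, ppos))

    edges: list[tuple[int, int, GlycosidicLinkage]] = []
    roots = []
    for k, (pidx, ppos) in enumerate(parents):
        if pidx == 0:
            roots.append(k)
            continue
        if not 1 <= pidx <= len(residues):
            raise _err("dangling-parent", f"tuple {k + 1} references missing parent {pidx}")
        if pidx - 1 == k:
            raise _err("dangling-parent", f"tuple {k + 1} is its own parent")
        child_pos = get_template(residues[k].symbol).anomeric_position
        link = GlycosidicLinkage(child_pos, None if ppos == 0 else ppos)
        edges.append((pidx - 1, k, link))
    if len(roots) != 1:
        raise _err("malformed-tree", f"expected exactly one root tuple, found {len(roots)}")
    return GlycanGraph(residues=residues, edges=edges, root_index=roots[0], spacer=spacer, source_text=code)


def encode_glycodigit(graph: GlycanGraph) -> str:
    """Inverse of :func:`parse_glycodigit` (exact round trip)."""
    parent_of: dict[int, tuple[int, GlycosidicLinkage]] = {}
    for p, c, l in graph.edges:
        parent_of[c] = (p, l)
    parts = []
    for i, r in enumerate(graph.residues):
        fields = [
            str(_RESIDUE_CODES[r.symbol]),
            str(_ANOMER_CODES[r.anomer]),
        ]
        if i in parent_of:
            p, l = parent_of[i]
            fields.append(str(l.parent_position or 0))
            fields.append(str(p + 1))
        else:
            fields.extend(["0", "0"])
        if r.substituents:
            fields.append("+".join(r.substituents))
        parts.append(".".join(fields))
    out = ";".join(parts)
    if graph.spacer:
        out += f"|{graph.spacer}"
    return out


# ---------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------

def validate_graph(graph: GlycanGraph) -> list[Diagnostic]:
    """All structural problems of a graph; empty list when valid."""
    diags: list[Diagnostic] = []

    for i, r in enumerate(graph.residues):
        if r.symbol not in REGISTRY:
            diags.append(Diagnostic("error", "unknown-residue", f"residue {i + 1}: unknown symbol {r.symbol!r}"))
    if any(d.code == "unknown-residue" for d in diags):
        return diags

    n = len(graph.residues)
    seen_children: set[int] = set()
    for p, c, _ in graph.edges:
        if not (0 <= p < n and 0 <= c < n):
            diags.append(Diagnostic("error", "bad-index", f"edge ({p},{c}) out of range"))
            return diags
        if c in seen_children:
            diags.append(Diagnostic("error", "multiple-parents", f"residue {c + 1} has several parents"))
        seen_children.add(c)
    if graph.root_index in seen_children or len(graph.edges) != n - 1:
        diags.append(Diagnostic("error", "not-a-tree", "edge set is not a tree rooted at the reducing end"))
    else:
        reach = {graph.root_index}
        stack = [graph.root_index]
        while stack:
            u = stack.pop()
            for c, _ in graph.children(u):
                if c in reach:
                    diags.append(Diagnostic("error", "not-a-tree", "cycle detected"))
                    return diags
                reach.add(c)
                stack.append(c)
        if len(reach) != n:
            diags.append(Diagnostic("error", "not-a-tree", "unreachable residues"))

    for i in range(n):
        tmpl = get_template(graph.residues[i].symbol)
        taken: dict[int, int] = {}
        sub_positions = set()
        for token in graph.residues[i].substituents:
            try:
                pos, code = parse_substituent(token)
            except ValueError:
                diags.append(Diagnostic("error", "malformed-substituent", f"residue {i + 1}: bad token {token!r}"))
                continue
            if code != "S":
                diags.append(Diagnostic("error", "unsupported-substituent", f"residue {i + 1}: {token!r}"))
            elif pos not in tmpl.acceptor_positions:
                diags.append(
                    Diagnostic("error", "invalid-substituent-position", f"residue {i + 1}: no free {pos}-OH for {token!r}")
                )
            else:
                sub_positions.add(pos)
        for c, l in graph.children(i):
            if l.child_position != get_template(graph.residues[c].symbol).anomeric_position:
                diags.append(
                    Diagnostic(
                        "error",
                        "child-position-mismatch",
                        f"residue {c + 1} links through carbon {l.child_position}, "
                        f"but its anomeric carbon is C{get_template(graph.residues[c].symbol).anomeric_position}",
                    )
                )
            if l.parent_position is None:
                continue
            if l.parent_position not in tmpl.acceptor_positions:
                diags.append(
                    Diagnostic(
                        "error",
                        "invalid-position",
                        f"residue {i + 1} ({graph.residues[i].symbol}) has no free hydroxyl at position {l.parent_position}",
                    )
                )
            elif l.parent_position in taken:
                diags.append(
                    Diagnostic("error", "duplicate-position", f"residue {i + 1}: position {l.parent_position} occupied twice")
                )
            elif l.parent_position in sub_positions:
                diags.append(
                    Diagnostic("error", "duplicate-position", f"residue {i + 1}: position {l.parent_position} carries a substituent")
                )
            else:
                taken[l.parent_position] = c
    return diags


# ---------------------------------------------------------------------
# list-file handling
# ---------------------------------------------------------------------

def iter_notation_lines(lines) -> list[tuple[str, str]]:
    """(identifier, notation) pairs from an input list.

    Lines are UTF-8 text, ``#`` comments and blanks skipped; an optional
    ``id<TAB>notation`` prefix overrides the default 1-based line-number
    identifier.
    """
    out: list[tuple[str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" in line:
            ident, _, rest = line.partition("\t")
            out.append((ident.strip(), rest.strip()))
        else:
            out.append((str(lineno), line.strip()))
    return out
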