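"""Independent oracles used by the test suite.

Each oracle re-derives an expected result by a different algorithm (and
where possible from independently stated facts, e.g. textbook
monosaccharide formulas) so that agreement with the package is a real
check rather than a tautology.
"""

from __future__ import annotations

import math
import re
from collections import Counter

from glylec.graph import GlycanGraph, GlycosidicLinkage, MonosaccharideRef, anomer_from_char

# ---------------------------------------------------------------------
# naive tokenizer-stack parser for condensed notation
# ---------------------------------------------------------------------

_SYMBOLS = [
    "GlcNAc", "GalNAc", "Neu5Ac", "Neu5Gc", "GlcA", "KDN",
    "Glc", "Gal", "Man", "Fuc", "Rha", "Xyl",
]
_TOKEN_RE = re.compile(
    r"(?:\[(?P<subs>[^\]]+)\])?"
    r"(?P<sym>" + "|".join(sorted(_SYMBOLS, key=len, reverse=True)) + r")"
    r"(?P<anomer>[ab?])?"
    r"(?:(?P<cpos>\d)-(?P<ppos>\d|\?))?"
)


def oracle_parse_condensed(text: str) -> GlycanGraph:
    """Parse by building a nested token structure with an explicit stack,
    then resolving attachments right-to-left (different algorithm from
    the package's recursive-descent parser)."""
    s = text.strip()
    spacer = None
    m = re.search(r"-(Sp\d+)$", s)
    if m:
        spacer = m.group(1)
        s = s[: m.start()]

    # pass 1: flat tokens via regex, explicit bracket stack for nesting
    items_stack: list[list] = [[]]
    i = 0
    while i < len(s):
        c = s[i]
        if c == "(":
            items_stack.append([])
            i += 1
        elif c == ")":
            sub = items_stack.pop()
            if not items_stack:
                raise ValueError("unbalanced )")
            items_stack[-1].append(sub)
            i += 1
        else:
            m = _TOKEN_RE.match(s, i)
            if not m or m.start() != i or m.end() == i:
                raise ValueError(f"cannot tokenize at {i}: {s[i:]!r}")
            d = m.groupdict()
            items_stack[-1].append(d)
            i = m.end()
    if len(items_stack) != 1:
        raise ValueError("unbalanced (")
    top = items_stack[0]

    residues: list[MonosaccharideRef] = []
    edges: list[tuple[int, int, GlycosidicLinkage]] = []

    def make(d: dict) -> int:
        subs = tuple(t.strip() for t in d["subs"].split(",")) if d["subs"] else ()
        residues.append(MonosaccharideRef(d["sym"], anomer_from_char(d["anomer"] or "?"), substituents=subs))
        return len(residues) - 1

    def link(child_idx: int, d: dict, parent_idx: int) -> None:
        cpos = int(d["cpos"])
        ppos = None if d["ppos"] == "?" else int(d["ppos"])
        edges.append((parent_idx, child_idx, GlycosidicLinkage(cpos, ppos)))

    def resolve(items: list) -> tuple[int, dict]:
        """Return (tail residue index, its token dict).  Attach every
        earlier item to the nearest plain residue to its right."""
        # indices of plain residues
        built = []  # (index in items, residue idx or (tail idx, dict))
        for it in items:
            if isinstance(it, list):
                built.append(("branch", resolve(it)))
            else:
                built.append(("residue", (make(it), it)))
        # find, for each position, the next plain residue to the right
        for k, (kind, payload) in enumerate(built):
            nxt = None
            for k2 in range(k + 1, len(built)):
                if built[k2][0] == "residue":
                    nxt = built[k2][1][0]
                    break
            if nxt is None:
                if k != len(built) - 1:
                    raise ValueError("no parent residue to the right")
                continue
            idx, d = payload
            if d["cpos"] is None:
                raise ValueError(f"residue {d['sym']} lacks a linkage")
            link(idx, d, nxt)
        kind, payload = built[-1]
        if kind != "residue":
            raise ValueError("chain ends in a branch")
        return payload

    if not top:
        raise ValueError("empty")
    root, d = resolve(top)
    if d["cpos"] is not None:
        raise ValueError("root carries a linkage")
    return GlycanGraph(residues=residues, edges=edges, root_index=root, spacer=spacer, source_text=text)


# ---------------------------------------------------------------------
# textbook formula arithmetic (independent of the package's tables)
# ---------------------------------------------------------------------

TEXTBOOK_FORMULAS: dict[str, Counter] = {
    "Glc": Counter({"C": 6, "H": 12, "O": 6}),
    "Gal": Counter({"C": 6, "H": 12, "O": 6}),
    "Man": Counter({"C": 6, "H": 12, "O": 6}),
    "GlcNAc": Counter({"C": 8, "H": 15, "N": 1, "O": 6}),
    "GalNAc": Counter({"C": 8, "H": 15, "N": 1, "O": 6}),
    "Fuc": Counter({"C": 6, "H": 12, "O": 5}),
    "Rha": Counter({"C": 6, "H": 12, "O": 5}),
    "Xyl": Counter({"C": 5, "H": 10, "O": 5}),
    "GlcA": Counter({"C": 6, "H": 10, "O": 7}),
    "Neu5Ac": Counter({"C": 11, "H": 19, "N": 1, "O": 9}),
    "Neu5Gc": Counter({"C": 11, "H": 19, "N": 1, "O": 10}),
    "KDN": Counter({"C": 9, "H": 16, "O": 9}),
}


def oracle_formula(graph: GlycanGraph) -> Counter:
    """Residue sum minus one water per edge, from the textbook table."""
    total: Counter = Counter()
    for r in graph.residues:
        total += TEXTBOOK_FORMULAS[r.symbol]
        for token in r.substituents:
            assert token.endswith("S"), token
            total += Counter({"S": 1, "O": 3})
    total["H"] -= 2 * len(graph.edges)
    total["O"] -= 1 * len(graph.edges)
    return +total


# ---------------------------------------------------------------------
# regex-based overlapping motif scan
# ---------------------------------------------------------------------

def pattern_to_regex(pattern: str) -> str:
    out = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "x":
            out.append(".")
            i += 1
        elif c == "[":
            j = pattern.index("]", i)
            out.append(pattern[i : j + 1])
            i = j + 1
        elif c == "{":
            j = pattern.index("}", i)
            members = pattern[i + 1 : j].lstrip("^")
            out.append(f"[^{members}]")
            i = j + 1
        else:
            out.append(re.escape(c))
            i += 1
    return "".join(out)


def oracle_scan(sequence: str, pattern: str) -> list[tuple[int, str]]:
    """All overlapping matches as (1-based start, matched substring)."""
    rx = re.compile(f"(?=({pattern_to_regex(pattern)}))")
    return [(m.start() + 1, m.group(1)) for m in rx.finditer(sequence)]


# ---------------------------------------------------------------------
# brute-force rank-by-vote consensus
# ---------------------------------------------------------------------

def oracle_consensus(
    scores: dict[str, dict[str, float | None]],
    orientations: dict[str, str],
    q: float,
) -> list[tuple[str, int, float]]:
    """Votes and mean ranks by explicit enumeration.

    ``scores[ligand][function]`` is the best pose score (None if
    missing).  Competition ranking: rank = 1 + number of strictly
    better ligands under the function's orientation.
    """
    ligands = sorted(scores)
    u = len(ligands)
    threshold = math.ceil(q * u)
    votes = {lig: 0 for lig in ligands}
    ranks: dict[str, list[int]] = {lig: [] for lig in ligands}
    for fn, orient in orientations.items():
        present = [lig for lig in ligands if scores[lig].get(fn) is not None]
        for lig in present:
            better = 0
            for other in present:
                if other == lig:
                    continue
                a, b = scores[other][fn], scores[lig][fn]
                if (orient == "higher_better" and a > b) or (orient == "lower_better" and a < b):
                    better += 1
            rank = 1 + better
            ranks[lig].append(rank)
            if rank <= threshold:
                votes[lig] += 1
    rows = [
        (lig, votes[lig], sum(ranks[lig]) / len(ranks[lig]) if ranks[lig] else math.inf)
        for lig in ligands
    ]
    rows.sort(key=lambda t: (-t[1], t[2], t[0]))
    return rows
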