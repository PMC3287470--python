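"""Lectin motif catalog, sequence scanning and context-based filtering.

Patterns use a restricted PROSITE-like grammar over the 20-letter amino
acid alphabet: literal residues, character classes ``[ST]``, negated
classes ``{^P}`` (the caret is optional, ``{P}`` means the same), and
the wildcard ``x``.  All overlapping matches are reported — biological
sites can overlap — and positions are 1-based with ``start`` at the
first matched residue, the convention used throughout the reports
(e.g. an EPN motif "at position 341" begins at residue 341).

Context filtering implements the false-positive rule used when reading
predictor output for a membrane receptor: a motif that only makes sense
in a particular topological compartment (a cytoplasmic kinase site, an
extracellular glycosylation sequon) is discarded unless its whole span
lies inside a segment of that kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: motif required_context values -> acceptable topology segment kind
CONTEXT_TO_SEGMENT = {
    "cytoplasmic": "inside",
    "extracellular": "outside",
    "transmembrane": "transmembrane",
}

CATEGORIES = frozenset(
    {"sugar-specificity", "calcium", "phospho-site", "adaptor-binding", "glycosylation", "other"}
)


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class MotifDefinition:
    """A compiled motif: per-position allowed residue sets."""

    id: str
    pattern: str
    category: str = "other"
    required_context: str = "any"
    source: str = ""
    positions: tuple[frozenset[str], ...] = ()

    @property
    def width(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int  # 1-based, first matched residue
    end: int  # 1-based inclusive
    matched: str
    sequence_id: str = ""


@dataclass(frozen=True)
class TopologySegment:
    kind: str  # "inside" | "transmembrane" | "outside"
    start: int
    end: int


@dataclass(frozen=True)
class TopologyAnnotation:
    """Non-overlapping segments jointly covering residues 1..length."""

    segments: tuple[TopologySegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty topology")
        pos = 1
        for seg in self.segments:
            if seg.kind not in ("inside", "transmembrane", "outside"):
                raise ValueError(f"unknown segment kind {seg.kind!r}")
            if seg.start != pos or seg.end < seg.start:
                raise ValueError(f"topology gap or overlap at position {pos} (segment {seg})")
            pos = seg.end + 1

    @property
    def length(self) -> int:
        return self.segments[-1].end

    @property
    def orientation(self) -> str:
        """type-II if the N-terminus is cytoplasmic, type-I if outside."""
        if not any(s.kind == "transmembrane" for s in self.segments):
            return "unknown"
        first = self.segments[0].kind
        return {"inside": "type-II", "outside": "type-I"}.get(first, "unknown")

    def segment_at(self, pos: int) -> TopologySegment:
        for seg in self.segments:
            if seg.start <= pos <= seg.end:
                return seg
        raise ValueError(f"position {pos} outside topology coverage 1..{self.length}")


# ---------------------------------------------------------------------
# pattern compilation and scanning
# ---------------------------------------------------------------------

def compile_motif(
    id: str,
    pattern: str,
    category: str = "other",
    required_context: str = "any",
    source: str = "",
) -> MotifDefinition:
    """Compile a restricted PROSITE-like pattern into a matcher."""
    if category not in CATEGORIES:
        raise PatternError(f"unknown category {category!r}")
    if required_context != "any" and required_context not in CONTEXT_TO_SEGMENT:
        raise PatternError(f"unknown required_context {required_context!r}")
    positions: list[frozenset[str]] = []
    i, n = 0, len(pattern)
    if n == 0:
        raise PatternError("empty pattern")
    while i < n:
        c = pattern[i]
        if c == "x":
            positions.append(AMINO_ACIDS)
            i += 1
        elif c in AMINO_ACIDS:
            positions.append(frozenset(c))
            i += 1
        elif c == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise PatternError(f"unbalanced '[' in {pattern!r}")
            members = pattern[i + 1 : j]
            if not members or not set(members) <= AMINO_ACIDS:
                raise PatternError(f"bad character class {pattern[i:j + 1]!r}")
            positions.append(frozenset(members))
            i = j + 1
        elif c == "{":
            j = pattern.find("}", i)
            if j < 0:
                raise PatternError(f"unbalanced '{{' in {pattern!r}")
            members = pattern[i + 1 : j]
            if members.startswith("^"):
                members = members[1:]
            if not members or not set(members) <= AMINO_ACIDS:
                raise PatternError(f"bad negated class {pattern[i:j + 1]!r}")
            positions.append(AMINO_ACIDS - set(members))
            i = j + 1
        else:
            raise PatternError(f"illegal pattern character {c!r} in {pattern!r}")
    return MotifDefinition(
        id=id,
        pattern=pattern,
        category=category,
        required_context=required_context,
        source=source,
        positions=tuple(positions),
    )


#: the sequon N-X-[ST], X != P
SEQUON = compile_motif("N-glyc-sequon", "N{^P}[ST]", "glycosylation", "extracellular", "builtin")


def default_catalog() -> list[MotifDefinition]:
    """The shipped lectin motif catalog.

    PKC / GSK3 / CtBP recognition patterns are deliberately not
    included: their exact patterns are server-side and would be guessed;
    users supply them via a catalog TSV instead.
    """
    return [
        compile_motif("EPN", "EPN", "sugar-specificity", "extracellular", "builtin"),
        compile_motif("WND", "WND", "calcium", "extracellular", "builtin"),
        compile_motif("hemi-ITAM", "YxxL", "adaptor-binding", "cytoplasmic", "builtin"),
        compile_motif("CKII", "[ST]xx[DE]", "phospho-site", "cytoplasmic", "builtin"),
        compile_motif("TRAF2", "[PSAT]x[QE]E", "adaptor-binding", "cytoplasmic", "builtin"),
        SEQUON,
    ]


def _check_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    return seq


def scan_motifs(
    sequence: str,
    catalog: list[MotifDefinition] | None = None,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All overlapping matches of every catalog motif, 1-based coordinates.

    Hits are sorted by (start, motif_id).
    """
    seq = _check_sequence(sequence)
    if catalog is None:
        catalog = default_catalog()
    hits: list[MotifHit] = []
    for motif in catalog:
        w = motif.width
        for s in range(len(seq) - w + 1):
            window = seq[s : s + w]
            if all(ch in allowed for ch, allowed in zip(window, motif.positions)):
                hits.append(MotifHit(motif.id, s + 1, s + w, window, sequence_id))
    hits.sort(key=lambda h: (h.start, h.motif_id))
    return hits


def find_sequons(sequence: str, sequence_id: str = "") -> list[MotifHit]:
    """N-X-[ST] sequons with X != P; start is the asparagine position."""
    return scan_motifs(sequence, [SEQUON], sequence_id)


# ---------------------------------------------------------------------
# context filtering and predictor consensus
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Rejection:
    hit: MotifHit
    rule: str


def filter_by_context(
    hits: list[MotifHit],
    topology: TopologyAnnotation,
    catalog: list[MotifDefinition] | None = None,
) -> tuple[list[MotifHit], list[Rejection]]:
    """Keep hits whose compartment matches their motif's required context.

    A hit is kept iff its motif's required_context is "any", or its full
    span lies inside one topology segment of the required kind.  Every
    rejection records the rule that fired.  kept + rejected partition
    the input; nothing is invented.
    """
    if catalog is None:
        catalog = default_catalog()
    by_id = {m.id: m for m in catalog}
    kept: list[MotifHit] = []
    rejected: list[Rejection] = []
    for hit in hits:
        if hit.start < 1 or hit.end > topology.length:
            raise ValueError(f"hit {hit} outside topology coverage 1..{topology.length}")
        motif = by_id.get(hit.motif_id)
        required = motif.required_context if motif is not None else "any"
        if required == "any":
            kept.append(hit)
            continue
        seg = topology.segment_at(hit.start)
        want = CONTEXT_TO_SEGMENT[required]
        if seg.kind == want and seg.end >= hit.end:
            kept.append(hit)
        elif seg.end < hit.end and topology.segment_at(hit.end) is not seg:
            rejected.append(Rejection(hit, f"span crosses a segment boundary; requires {required}"))
        else:
            rejected.append(
                Rejection(hit, f"requires {required} ({want}) but lies in {seg.kind} {seg.start}..{seg.end}")
            )
    return kept, rejected


@dataclass(frozen=True)
class ConsensusFeature:
    feature: str
    start: int
    predictors: tuple[str, ...]

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)


def consensus_features(
    hit_lists: dict[str, list],
    k: int = 2,
    window: int = 0,
) -> list[ConsensusFeature]:
    """Features reported by >= k predictors at the same start.

    ``hit_lists`` maps predictor name to its hits; each hit is either a
    :class:`MotifHit`, a ``(feature, start)`` pair, or a bare integer
    start (feature name then defaults to "").  Agreement is exact-start
    by default; ``window`` allows +-w clustering (greedy, by ascending
    start, anchored at each cluster's first seen start).  The result is
    monotone in k: raising k can only shrink it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records: list[tuple[str, int, str]] = []  # (feature, start, predictor)
    for predictor, hits in hit_lists.items():
        for h in hits:
            if isinstance(h, MotifHit):
                records.append((h.motif_id, h.start, predictor))
            elif isinstance(h, int):
                records.append(("", h, predictor))
            else:
                feature, start = h
                records.append((str(feature), int(start), predictor))

    out: list[ConsensusFeature] = []
    by_feature: dict[str, list[tuple[int, str]]] = {}
    for feature, start, predictor in records:
        by_feature.setdefault(feature, []).append((start, predictor))
    for feature, items in sorted(by_feature.items()):
        items.sort()
        clusters: list[tuple[int, dict[str, None]]] = []  # (anchor start, predictors)
        for start, predictor in items:
            if clusters and abs(start - clusters[-1][0]) <= window:
                clusters[-1][1].setdefault(predictor)
            else:
                clusters.append((start, {predictor: None}))
        for anchor, predictors in clusters:
            if len(predictors) >= k:
                out.append(ConsensusFeature(feature, anchor, tuple(sorted(predictors))))
    out.sort(key=lambda f: (f.start, f.feature))
    return out


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(sequence_id, sequence) pairs; id is the first header token."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def read_feature_table(path: str | Path) -> dict[str, list[MotifHit]]:
    """Per-predictor hits from a TSV with columns
    predictor, sequence_id, feature, start, end."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["predictor", "sequence_id", "feature", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    out: dict[str, list[MotifHit]] = {}
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric coordinates in row {tuple(row)}") from None
        out.setdefault(str(row.predictor), []).append(
            MotifHit(str(row.feature), start, end, "", str(row.sequence_id))
        )
    return out


def read_topology(path: str | Path) -> TopologyAnnotation:
    """TopologyAnnotation from a TSV with columns kind, start, end."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("kind", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"topology table missing columns: {missing}")
    segs = []
    for row in df.itertuples(index=False):
        try:
            segs.append(TopologySegment(str(row.kind), int(row.start), int(row.end)))
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric coordinates in row {tuple(row)}") from None
    segs.sort(key=lambda s: s.start)
    return TopologyAnnotation(tuple(segs))


def hits_to_tsv(hits: list[MotifHit]) -> str:
    lines = ["sequence_id\tmotif_id\tstart\tend\tmatched"]
    lines += [f"{h.sequence_id}\t{h.motif_id}\t{h.start}\t{h.end}\t{h.matched}" for h in hits]
    return "\n".join(lines) + "\n"


def hits_to_gff3(hits: list[MotifHit]) -> str:
    """GFF3 over protein coordinates (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for n, h in enumerate(hits, start=1):
        attrs = f"ID=motif{n};Name={h.motif_id}"
        if h.matched:
            attrs += f";match={h.matched}"
        lines.append(
            f"{h.sequence_id or '.'}\tglylec\tsequence_motif\t{h.start}\t{h.end}\t.\t.\t.\t{attrs}"
        )
    return "\n".join(lines) + "\n"
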