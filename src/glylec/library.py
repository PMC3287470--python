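"""Batch conversion of notation lists into an in-silico screening library.

A library build never aborts on a bad entry: every line is parsed,
validated and emitted independently, and failures are captured with the
diagnostic code that fired, so the manifest doubles as a conversion
coverage report (converted / total).  Terminal residues — the leaves of
each glycan tree, the sugars a lectin actually contacts — are annotated
per entry for downstream binding-profile analysis.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .assembly import AssemblyError, emit_smiles, molecular_formula, sdf_record, smiles_record
from ._chem import formula_to_string
from .graph import GlycanGraph, MonosaccharideRef, NotationError
from .notation import iter_notation_lines, parse_condensed, parse_glycodigit


def terminal_residues(graph: GlycanGraph) -> frozenset[MonosaccharideRef]:
    """Leaf residues at the non-reducing end(s), with their anomers.

    A single-residue glycan terminates with itself, so monosaccharide
    controls join terminal-profile denominators.
    """
    return frozenset(graph.residues[i] for i in graph.leaves())


@dataclass
class LibraryEntry:
    identifier: str
    source_text: str
    status: str  # "converted" | "failed"
    failure_reason: str = ""
    smiles: str = ""
    terminal_residues: frozenset[MonosaccharideRef] = frozenset()
    formula: str = ""
    flags: tuple[str, ...] = ()
    graph: GlycanGraph | None = None
    assembled: object | None = None


@dataclass
class LibraryManifest:
    entries: list[LibraryEntry] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.entries)

    @property
    def n_converted(self) -> int:
        return sum(1 for e in self.entries if e.status == "converted")

    @property
    def coverage(self) -> float:
        return self.n_converted / self.n_total if self.entries else 0.0

    @property
    def coverage_percent(self) -> float:
        """Coverage as a percentage rounded to one decimal."""
        return round(100.0 * self.coverage, 1)

    def converted(self) -> list[LibraryEntry]:
        return [e for e in self.entries if e.status == "converted"]

    def failed(self) -> list[LibraryEntry]:
        return [e for e in self.entries if e.status == "failed"]

    def by_id(self) -> dict[str, LibraryEntry]:
        return {e.identifier: e for e in self.entries}

    def to_json_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_converted": self.n_converted,
            "coverage": self.coverage,
            "coverage_percent": self.coverage_percent,
            "entries": [
                {
                    "identifier": e.identifier,
                    "source_text": e.source_text,
                    "status": e.status,
                    "failure_reason": e.failure_reason,
                    "smiles": e.smiles,
                    "formula": e.formula,
                    "flags": list(e.flags),
                    "terminal_residues": sorted(
                        f"{r.symbol}:{r.anomer}" for r in e.terminal_residues
                    ),
                }
                for e in self.entries
            ],
        }


def build_library(
    lines: list[str] | list[tuple[str, str]],
    fmt: str = "iupac",
) -> LibraryManifest:
    """Parse, validate and emit every entry of a notation list.

    ``lines`` may be raw text lines (comments/blanks skipped, 1-based
    line-number identifiers, optional ``id<TAB>notation``) or explicit
    ``(identifier, notation)`` pairs.  ``fmt`` selects the notation
    dialect ("iupac" or "glycodigit").
    """
    if fmt not in ("iupac", "glycodigit"):
        raise ValueError(f"unknown format {fmt!r}")
    parse = parse_condensed if fmt == "iupac" else parse_glycodigit
    if lines and isinstance(lines[0], (tuple, list)):
        pairs = [(str(i), str(t)) for i, t in lines]
    else:
        pairs = iter_notation_lines([str(x) for x in lines])
    if not pairs:
        raise ValueError("empty input list")

    manifest = LibraryManifest()
    for ident, text in pairs:
        try:
            graph = parse(text)
            assembled = emit_smiles(graph)
        except (NotationError, AssemblyError) as exc:
            manifest.entries.append(
                LibraryEntry(
                    identifier=ident,
                    source_text=text,
                    status="failed",
                    failure_reason=exc.code,
                )
            )
            continue
        manifest.entries.append(
            LibraryEntry(
                identifier=ident,
                source_text=text,
                status="converted",
                smiles=assembled.smiles,
                terminal_residues=terminal_residues(graph),
                formula=formula_to_string(molecular_formula(graph)),
                flags=tuple(assembled.flags),
                graph=graph,
                assembled=assembled,
            )
        )
    return manifest


def export_library(manifest: LibraryManifest, directory: str | Path, fmt: str = "smiles") -> dict[str, Path]:
    """Write converted entries plus manifest.json and failures.tsv.

    Returns the paths written, keyed by role ("records", "manifest",
    "failures").
    """
    if fmt not in ("smiles", "sdf"):
        raise ValueError(f"unknown export format {fmt!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    if fmt == "smiles":
        records_path = directory / "library.smi"
        body = "\n".join(smiles_record(e.identifier, e.assembled) for e in manifest.converted())
    else:
        records_path = directory / "library.sdf"
        body = "\n".join(sdf_record(e.identifier, e.assembled, e.source_text) for e in manifest.converted())
    records_path.write_text(body + ("\n" if body else ""))

    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.to_json_dict(), indent=2) + "\n")

    failures_path = directory / "failures.tsv"
    rows = ["identifier\tsource_text\tfailure_reason"]
    rows += [f"{e.identifier}\t{e.source_text}\t{e.failure_reason}" for e in manifest.failed()]
    failures_path.write_text("\n".join(rows) + "\n")

    return {"records": records_path, "manifest": manifest_path, "failures": failures_path}


@dataclass
class ConformerIndex:
    """Per-entry conformer counts ingested from an external generator."""

    counts: dict[str, int] = field(default_factory=dict)
    sdf_paths: dict[str, Path] = field(default_factory=dict)

    @property
    def enabled(self) -> bool:
        return bool(self.counts) or bool(self.sdf_paths)


def conformer_hook(
    manifest: LibraryManifest,
    command_template: str | None,
    workdir: str | Path | None = None,
) -> ConformerIndex:
    """Run an external 3-D conformer generator over the library.

    ``command_template`` is a shell template with ``{input}`` and
    ``{output}`` placeholders; each converted entry is written as a
    single-record SDF, the command is invoked once per entry, and the
    multi-record SDF it produces is ingested (conformers counted by
    ``$$$$`` record delimiters).  The toolkit itself computes no 3-D
    coordinates.  If the template is unset or its executable is absent
    the feature is disabled with a warning and the manifest untouched.
    """
    index = ConformerIndex()
    if not command_template:
        warnings.warn("conformer hook not configured; skipping 3-D generation", stacklevel=2)
        return index
    exe = command_template.split()[0]
    if shutil.which(exe) is None:
        warnings.warn(f"conformer tool {exe!r} not found on PATH; skipping", stacklevel=2)
        return index

    base = Path(workdir) if workdir is not None else Path(tempfile.mkdtemp(prefix="glylec-conf-"))
    base.mkdir(parents=True, exist_ok=True)
    for entry in manifest.converted():
        inp = base / f"{entry.identifier}.in.sdf"
        out = base / f"{entry.identifier}.conf.sdf"
        inp.write_text(sdf_record(entry.identifier, entry.assembled, entry.source_text) + "\n")
        cmd = command_template.format(input=str(inp), output=str(out))
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0 or not out.exists():
            warnings.warn(f"conformer generation failed for entry {entry.identifier}", stacklevel=2)
            continue
        n = out.read_text().count("$$$$")
        index.counts[entry.identifier] = n
        index.sdf_paths[entry.identifier] = out
    return index
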