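"""Consensus re-ranking of docking poses and terminal-sugar profiling.

Poses from several docking protocols are re-scored by a panel of
scoring functions; because the functions live on incomparable scales,
they are combined by *rank-by-vote* consensus: per site, each function
ranks the ligands by its best pose (orientation-aware, competition
ranking, ties share the better rank), and a ligand earns one vote from
each function that places it within the top ``ceil(q * U)`` of the
``U`` unique ligands.  Ligands are then ordered by votes (descending),
mean rank (ascending), ligand id — and the top ``ceil(f * U)`` unique
ligands are selected.  Ceiling selection guarantees at least one ligand
survives.  A ligand missing a function's score simply collects no vote
from that function.

The terminal-binding profile answers "which terminal sugars does this
lectin prefer": for each terminal monosaccharide (with anomer), the
proportion of library glycans carrying that terminal that made the
selected set.  Branched glycans count once per distinct terminal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .graph import MonosaccharideRef, anomer_to_char
from .library import LibraryManifest

_META_COLUMNS = ("ligand_id", "site_id", "pose_id")


@dataclass(frozen=True)
class ScoringFunctionSpec:
    name: str
    orientation: str  # "higher_better" | "lower_better"

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_better", "lower_better"):
            raise ValueError(f"bad orientation {self.orientation!r}")


def default_functions() -> list[ScoringFunctionSpec]:
    """The standard re-scoring panel and its orientations."""
    return [
        ScoringFunctionSpec("LigScore1", "higher_better"),
        ScoringFunctionSpec("LigScore2", "higher_better"),
        ScoringFunctionSpec("PLP1", "lower_better"),
        ScoringFunctionSpec("PLP2", "lower_better"),
        ScoringFunctionSpec("Jain", "higher_better"),
        ScoringFunctionSpec("PMF", "lower_better"),
    ]


@dataclass
class ConsensusRanking:
    site_id: str
    #: (ligand_id, votes, mean_rank), ordered by
    #: (votes desc, mean_rank asc, ligand_id asc)
    ranked: list[tuple[str, int, float]]
    q: float
    f: float | None = None

    @property
    def ligands(self) -> list[str]:
        return [lig for lig, _, _ in self.ranked]


def read_pose_table(path: str | Path) -> pd.DataFrame:
    """Poses TSV with header ligand_id, site_id, pose_id, <function...>."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _META_COLUMNS})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose table missing columns: {missing}")
    return df


def read_functions(path: str | Path) -> list[ScoringFunctionSpec]:
    """Scoring-function orientation config (TSV: name, orientation)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("name", "orientation") if c not in df.columns]
    if missing:
        raise ValueError(f"function table missing columns: {missing}")
    return [ScoringFunctionSpec(str(r.name), str(r.orientation)) for r in df.itertuples(index=False)]


def best_pose_table(
    poses: pd.DataFrame,
    functions: list[ScoringFunctionSpec] | None = None,
) -> pd.DataFrame:
    """Best score per (site, ligand) for each function independently.

    "Best" respects each function's orientation (max for higher_better,
    min for lower_better); missing scores stay missing.
    """
    if functions is None:
        functions = default_functions()
    if poses.empty:
        raise ValueError("empty pose table")
    known = {f.name for f in functions}
    score_cols = [c for c in poses.columns if c not in _META_COLUMNS]
    unknown = sorted(set(score_cols) - known)
    if unknown:
        raise ValueError(f"scores for unregistered functions: {unknown}")
    grouped = poses.groupby(["site_id", "ligand_id"], sort=True)
    pieces = {}
    for f in functions:
        if f.name not in poses.columns:
            continue
        col = grouped[f.name]
        pieces[f.name] = col.max() if f.orientation == "higher_better" else col.min()
    return pd.DataFrame(pieces).reset_index()


def consensus_rank(
    table: pd.DataFrame,
    q: float = 0.25,
    functions: list[ScoringFunctionSpec] | None = None,
) -> dict[str, ConsensusRanking]:
    """Rank-by-vote consensus per site from a best-pose table.

    For every scoring function the site's ligands are ranked
    (competition ranking: tied scores share the better rank) and each
    ligand within the top ``ceil(q * U)`` ranks earns one vote.
    Returns one :class:`ConsensusRanking` per site.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if functions is None:
        functions = default_functions()
    spec = {f.name: f for f in functions}
    out: dict[str, ConsensusRanking] = {}
    for site_id, sub in table.groupby("site_id", sort=True):
        ligands = sorted(sub["ligand_id"])
        u = len(ligands)
        threshold = math.ceil(q * u)
        sub = sub.set_index("ligand_id").loc[ligands]
        votes = {lig: 0 for lig in ligands}
        rank_sums = {lig: [] for lig in ligands}
        for name, f in spec.items():
            if name not in sub.columns:
                continue
            scores = sub[name].to_numpy(dtype=float)
            oriented = -scores if f.orientation == "higher_better" else scores
            mask = ~np.isnan(oriented)
            if not mask.any():
                continue
            ranks = np.full(u, np.nan)
            ranks[mask] = rankdata(oriented[mask], method="min")
            for lig, r in zip(ligands, ranks):
                if np.isnan(r):
                    continue
                rank_sums[lig].append(r)
                if r <= threshold:
                    votes[lig] += 1
        ranked = sorted(
            (
                (lig, votes[lig], float(np.mean(rank_sums[lig])) if rank_sums[lig] else math.inf)
                for lig in ligands
            ),
            key=lambda t: (-t[1], t[2], t[0]),
        )
        out[str(site_id)] = ConsensusRanking(site_id=str(site_id), ranked=ranked, q=q)
    return out


def select_top_fraction(ranking: ConsensusRanking, f: float = 0.25) -> list[str]:
    """The first ``ceil(f * U)`` unique ligands of a consensus ranking."""
    if not 0 < f <= 1:
        raise ValueError("f must be in (0, 1]")
    u = len(ranking.ranked)
    return [lig for lig, _, _ in ranking.ranked[: math.ceil(f * u)]]


@dataclass(frozen=True)
class TerminalProfileRow:
    site_id: str
    terminal: MonosaccharideRef
    n_library: int
    n_selected: int

    @property
    def proportion(self) -> float:
        return self.n_selected / self.n_library


def terminal_binding_profile(
    selected: dict[str, list[str] | set[str]],
    manifest: LibraryManifest,
) -> list[TerminalProfileRow]:
    """Per-(site, terminal sugar) docked proportions.

    For each terminal monosaccharide t: |selected glycans terminating in
    t| / |converted library glycans terminating in t|.  Glycans with
    several distinct terminals count toward each; terminals absent from
    the library are omitted (no 0/0 rows).
    """
    by_id = {e.identifier: e for e in manifest.converted()}
    # library denominators: terminal -> glycan ids
    denom: dict[MonosaccharideRef, set[str]] = {}
    for e in by_id.values():
        for t in e.terminal_residues:
            key = MonosaccharideRef(t.symbol, t.anomer)
            denom.setdefault(key, set()).add(e.identifier)
    rows: list[TerminalProfileRow] = []
    for site_id in sorted(selected):
        ids = set(selected[site_id])
        unknown = ids - set(by_id)
        if unknown:
            raise ValueError(f"selected ligands not in the converted library: {sorted(unknown)}")
        for terminal in sorted(denom, key=lambda r: (r.symbol, r.anomer)):
            members = denom[terminal]
            n_sel = len(members & ids)
            rows.append(TerminalProfileRow(site_id, terminal, len(members), n_sel))
    return rows


def profile_to_tsv(rows: list[TerminalProfileRow]) -> str:
    lines = ["site_id\tterminal\tanomer\tn_library\tn_selected\tproportion"]
    for r in rows:
        lines.append(
            f"{r.site_id}\t{r.terminal.symbol}\t{anomer_to_char(r.terminal.anomer)}"
            f"\t{r.n_library}\t{r.n_selected}\t{r.proportion:.4f}"
        )
    return "\n".join(lines) + "\n"


def ranking_to_tsv(ranking: ConsensusRanking) -> str:
    lines = ["ligand_id\tvotes\tmean_rank"]
    for lig, votes, mean_rank in ranking.ranked:
        mr = "" if math.isinf(mean_rank) else f"{mean_rank:.3f}"
        lines.append(f"{lig}\t{votes}\t{mr}")
    return "\n".join(lines) + "\n"
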