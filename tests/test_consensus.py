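"""Best-pose reduction, rank-by-vote consensus, selection, terminal profiling."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glylec.consensus import (
    ScoringFunctionSpec,
    best_pose_table,
    consensus_rank,
    default_functions,
    read_pose_table,
    select_top_fraction,
    terminal_binding_profile,
)
from glylec.fixtures import ScoreTableParams, synthetic_score_table
from glylec.graph import ALPHA, MonosaccharideRef
from glylec.library import build_library

from oracles import oracle_consensus


def poses_df(rows, functions):
    cols = ["ligand_id", "site_id", "pose_id"] + [f.name for f in functions]
    return pd.DataFrame(rows, columns=cols)


HB = ScoringFunctionSpec("LigScore1", "higher_better")
LB = ScoringFunctionSpec("PMF", "lower_better")


class TestBestPoseTable:
    def test_orientation_aware_best(self):
        df = poses_df(
            [
                ["L1", "s1", "p1", 3.0, -20.0],
                ["L1", "s1", "p2", 7.0, -35.0],
            ],
            [HB, LB],
        )
        best = best_pose_table(df, [HB, LB])
        row = best.iloc[0]
        assert row["LigScore1"] == 7.0 and row["PMF"] == -35.0

    def test_sites_are_independent(self):
        df = poses_df(
            [
                ["L1", "s1", "p1", 1.0, -1.0],
                ["L1", "s2", "p1", 9.0, -9.0],
            ],
            [HB, LB],
        )
        best = best_pose_table(df, [HB, LB])
        assert len(best) == 2
        assert set(best["site_id"]) == {"s1", "s2"}

    def test_unregistered_function_rejected(self):
        df = poses_df([["L1", "s1", "p1", 1.0]], [ScoringFunctionSpec("Mystery", "higher_better")])
        with pytest.raises(ValueError, match="unregistered"):
            best_pose_table(df, [HB])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            best_pose_table(poses_df([], [HB]), [HB])


class TestConsensusRank:
    def test_unanimous_winner(self):
        functions = default_functions()
        rows = []
        for i in range(4):
            lig = f"L{i + 1}"
            vals = []
            for f in functions:
                good = 10.0 if f.orientation == "higher_better" else -10.0
                bad = float(i) if f.orientation == "higher_better" else -float(i)
                vals.append(good if lig == "L1" else bad)
            rows.append([lig, "s1", "p1"] + vals)
        best = best_pose_table(poses_df(rows, functions), functions)
        ranking = consensus_rank(best, q=0.25, functions=functions)["s1"]
        lig, votes, mean_rank = ranking.ranked[0]
        assert (lig, votes, mean_rank) == ("L1", 6, 1.0)

    def test_constant_scores_tie_break_by_ligand_id(self):
        rows = [[f"L{i}", "s1", "p1", 5.0, 5.0] for i in (3, 1, 2)]
        best = best_pose_table(poses_df(rows, [HB, LB]), [HB, LB])
        ranking = consensus_rank(best, q=0.5, functions=[HB, LB])["s1"]
        assert ranking.ligands == ["L1", "L2", "L3"]
        # competition ranking: all tied at rank 1, so everyone votes
        assert all(v == 2 for _, v, _ in ranking.ranked)

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        functions = default_functions()
        for trial in range(25):
            n_lig = int(rng.integers(2, 12))
            fns = list(rng.choice(functions, size=int(rng.integers(1, len(functions) + 1)), replace=False))
            q = float(rng.choice([0.1, 0.25, 0.5, 1.0]))
            scores = {}
            rows = []
            for i in range(n_lig):
                lig = f"L{i:02d}"
                # coarse grid to force plenty of ties
                vals = {f.name: float(np.round(rng.integers(-3, 4) + 0.5 * rng.integers(0, 2), 1)) for f in fns}
                if rng.random() < 0.2:
                    dropped = str(rng.choice([f.name for f in fns]))
                    vals[dropped] = None
                scores[lig] = vals
                rows.append([lig, "s1", "p1"] + [np.nan if vals[f.name] is None else vals[f.name] for f in fns])
            best = best_pose_table(poses_df(rows, fns), fns)
            got = consensus_rank(best, q=q, functions=fns)["s1"].ranked
            want = oracle_consensus(scores, {f.name: f.orientation for f in fns}, q)
            for (gl, gv, gm), (wl, wv, wm) in zip(got, want):
                assert (gl, gv) == (wl, wv), (trial, got, want)
                assert (math.isinf(gm) and math.isinf(wm)) or gm == pytest.approx(wm)

    def test_permutation_invariance(self):
        tsv, _, functions = synthetic_score_table(ScoreTableParams(seed=5))
        df = read_pose_table(io.StringIO(tsv))
        shuffled = df.sample(frac=1.0, random_state=11).reset_index(drop=True)
        a = consensus_rank(best_pose_table(df, functions), functions=functions)
        b = consensus_rank(best_pose_table(shuffled, functions), functions=functions)
        assert {s: r.ranked for s, r in a.items()} == {s: r.ranked for s, r in b.items()}

    def test_monotonicity_improving_scores_never_loses_votes(self):
        rng = np.random.default_rng(3)
        functions = default_functions()
        rows = [
            [f"L{i}", "s1", "p1"] + [float(np.round(rng.normal(), 1)) for _ in functions]
            for i in range(8)
        ]
        df = poses_df(rows, functions)
        best = best_pose_table(df, functions)
        before = dict(
            (lig, v) for lig, v, _ in consensus_rank(best, functions=functions)["s1"].ranked
        )
        improved = df.copy()
        for f in functions:
            delta = 5.0 if f.orientation == "higher_better" else -5.0
            improved.loc[improved["ligand_id"] == "L3", f.name] += delta
        after = dict(
            (lig, v)
            for lig, v, _ in consensus_rank(best_pose_table(improved, functions), functions=functions)["s1"].ranked
        )
        assert after["L3"] >= before["L3"]

    def test_q_out_of_range(self):
        best = best_pose_table(poses_df([["L1", "s1", "p1", 1.0]], [HB]), [HB])
        for q in (0, -0.1, 1.5):
            with pytest.raises(ValueError):
                consensus_rank(best, q=q, functions=[HB])


class TestSelectTopFraction:
    @pytest.mark.parametrize("u,f,expected", [(12, 0.25, 3), (10, 0.25, 3), (7, 1.0, 7), (1, 0.1, 1)])
    def test_ceiling_examples(self, u, f, expected):
        rows = [[f"L{i:03d}", "s1", "p1", float(i)] for i in range(u)]
        best = best_pose_table(poses_df(rows, [HB]), [HB])
        ranking = consensus_rank(best, functions=[HB])["s1"]
        assert len(select_top_fraction(ranking, f)) == expected

    @settings(max_examples=120, derandomize=True)
    @given(u=st.integers(1, 100), f=st.sampled_from([0.1, 0.25, 0.5, 1.0]))
    def test_size_is_ceil_fu(self, u, f):
        rows = [[f"L{i:03d}", "s1", "p1", float(i)] for i in range(u)]
        best = best_pose_table(poses_df(rows, [HB]), [HB])
        ranking = consensus_rank(best, functions=[HB])["s1"]
        sel = select_top_fraction(ranking, f)
        assert len(sel) == math.ceil(f * u)
        assert len(set(sel)) == len(sel)

    def test_fraction_out_of_range(self):
        rows = [["L1", "s1", "p1", 1.0]]
        ranking = consensus_rank(best_pose_table(poses_df(rows, [HB]), [HB]), functions=[HB])["s1"]
        with pytest.raises(ValueError):
            select_top_fraction(ranking, 0)


class TestPlantedRecovery:
    def test_noiseless_recovery_is_exact(self):
        params = ScoreTableParams(n_ligands=16, planted_top=4, noise_scale=0.0, seed=9)
        tsv, planted, functions = synthetic_score_table(params)
        best = best_pose_table(read_pose_table(io.StringIO(tsv)), functions)
        for site, ranking in consensus_rank(best, q=4 / 16, functions=functions).items():
            assert set(select_top_fraction(ranking, 4 / 16)) == set(planted)

    def test_recovery_with_margin_over_noise(self):
        params = ScoreTableParams(n_ligands=24, planted_top=6, noise_scale=0.5, seed=13)
        tsv, planted, functions = synthetic_score_table(params)
        best = best_pose_table(read_pose_table(io.StringIO(tsv)), functions)
        for ranking in consensus_rank(best, q=0.25, functions=functions).values():
            assert set(select_top_fraction(ranking, 0.25)) == set(planted)


class TestTerminalProfile:
    @pytest.fixture()
    def manifest(self):
        return build_library(
            [
                ("g1", "Mana1-2Mana"),        # terminal Man(a)
                ("g2", "Mana1-3Galb"),        # terminal Man(a)
                ("g3", "Galb1-4(Fuca1-3)GlcNAcb"),  # terminals Gal(b), Fuc(a)
                ("g4", "Neu5Aca2-3Galb1-4Glcb"),    # terminal Neu5Ac(a)
            ]
        )

    def test_direct_count(self, manifest):
        rows = terminal_binding_profile({"site1": {"g1"}}, manifest)
        by_term = {(r.terminal.symbol, r.terminal.anomer): r for r in rows}
        man = by_term[("Man", ALPHA)]
        assert (man.n_library, man.n_selected, man.proportion) == (2, 1, 0.5)

    def test_absent_terminal_omitted(self, manifest):
        rows = terminal_binding_profile({"site1": set()}, manifest)
        assert all(r.n_library > 0 for r in rows)
        assert ("Xyl",) not in {(r.terminal.symbol,) for r in rows}

    def test_branched_counts_toward_each_terminal(self, manifest):
        rows = terminal_binding_profile({"site1": {"g3"}}, manifest)
        by_term = {(r.terminal.symbol): r for r in rows}
        assert by_term["Gal"].n_selected == 1 and by_term["Fuc"].n_selected == 1
        # brute-force recount
        for r in rows:
            n_lib = sum(
                1
                for e in manifest.converted()
                if any(t.symbol == r.terminal.symbol and t.anomer == r.terminal.anomer for t in e.terminal_residues)
            )
            assert r.n_library == n_lib

    def test_proportions_bounded(self, manifest):
        rows = terminal_binding_profile({"site1": {"g1", "g3", "g4"}}, manifest)
        for r in rows:
            assert 0.0 <= r.proportion <= 1.0
            assert r.n_selected <= r.n_library

    def test_unknown_ligand_rejected(self, manifest):
        with pytest.raises(ValueError, match="not in the converted library"):
            terminal_binding_profile({"site1": {"nope"}}, manifest)
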