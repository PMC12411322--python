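"""Marker pipeline, GRM and pedigree-kinship tests."""

import numpy as np
import pandas as pd
import pytest

from metfa.errors import InputError, PedigreeError
from metfa.genetics import (MarkerMatrix, compute_cop, compute_grm, filter_markers,
                            impute_markers, parse_purdy, prune_markers)


def mm(arr, genos=None, markers=None):
    arr = np.asarray(arr, float)
    genos = genos or [f"g{i}" for i in range(arr.shape[0])]
    markers = markers or [f"m{j}" for j in range(arr.shape[1])]
    return MarkerMatrix(pd.DataFrame(arr, index=genos, columns=markers))


class TestFilter:
    def test_hand_audited_toy_table(self):
        rng = np.random.default_rng(0)
        n = 40
        base = rng.choice([-1.0, 1.0], size=n)
        cols = {
            "ok": base,
            "too_missing": base.copy(),            # 10% missing -> removed
            "low_maf": np.full(n, 1.0),            # monomorphic -> removed
            "boundary_maf": np.r_[np.full(1, -1.0), np.full(n - 1, 1.0)],  # maf 0.025 -> kept
            "too_het": np.r_[np.zeros(5), base[5:]],  # 12.5% het -> removed
            "het_boundary": np.r_[np.zeros(4), base[4:]],  # 10% het -> kept
        }
        X = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        X.iloc[:4, 1] = np.nan
        out = filter_markers(MarkerMatrix(X))
        assert list(out.calls.columns) == ["ok", "boundary_maf", "het_boundary"]

    def test_six_percent_missing_removed_five_kept(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.choice([-1.0, 1.0], size=(100, 2)),
                         columns=["m6", "m5"])
        X.iloc[:6, 0] = np.nan
        X.iloc[:5, 1] = np.nan
        out = filter_markers(MarkerMatrix(X))
        assert list(out.calls.columns) == ["m5"]

    def test_all_removed_is_error(self):
        X = pd.DataFrame({"mono": np.ones(10)})
        with pytest.raises(InputError):
            filter_markers(MarkerMatrix(X))


class TestPrune:
    def test_identical_pair_keeps_first(self):
        rng = np.random.default_rng(2)
        a = rng.choice([-1.0, 1.0], 50)
        out, removed = prune_markers(mm(np.column_stack([a, a, -a])))
        assert list(out.calls.columns) == ["m0"]
        assert set(removed) == {"m1", "m2"}

    def test_independent_markers_survive(self):
        rng = np.random.default_rng(3)
        X = rng.choice([-1.0, 1.0], size=(200, 3))
        out, removed = prune_markers(mm(X))
        assert out.calls.shape[1] == 3 and not removed

    def test_sequential_rule_matches_hand_replay(self):
        # correlation chain: m0~m1 strongly, m1~m2 strongly, m0~m2 weakly.
        # scanning in order removes m1 (linked to m0) but keeps m2, which a
        # clustering approach would have merged away.
        rng = np.random.default_rng(4)
        a = rng.choice([-1.0, 1.0], 400)
        b = np.where(rng.random(400) < 0.95, a, -a)     # r(a,b) ~ 0.9
        c = np.where(rng.random(400) < 0.95, b, -b)     # r(b,c) ~ 0.9, r(a,c) ~ 0.8
        X = np.column_stack([a, b, c])
        corr = np.corrcoef(X, rowvar=False)
        out, removed = prune_markers(mm(X))
        # replay the printed rule by hand on the same correlation matrix
        expected_removed = set()
        names = ["m0", "m1", "m2"]
        for i in range(3):
            if names[i] in expected_removed:
                continue
            for j in range(i + 1, 3):
                if names[j] not in expected_removed and abs(corr[i, j]) > 0.8:
                    expected_removed.add(names[j])
        assert set(removed) == expected_removed

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(5)
        a = rng.choice([-1.0, 1.0], 100)
        X = np.column_stack([a, np.where(rng.random(100) < 0.9, a, -a),
                             rng.choice([-1.0, 1.0], 100)])
        once, _ = prune_markers(mm(X))
        twice, removed2 = prune_markers(once)
        assert list(twice.calls.columns) == list(once.calls.columns) and not removed2


class TestGRM:
    def test_two_genotype_printed_example(self):
        grm = compute_grm(mm([[1.0], [-1.0]]))
        assert np.allclose(grm.values.to_numpy(), [[2.0, -2.0], [-2.0, 2.0]])

    def test_row_sums_symmetry_psd_and_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.choice([-1.0, 0.0, 1.0], size=(20, 50), p=[0.45, 0.1, 0.45])
        grm = compute_grm(mm(X)).values.to_numpy()
        assert np.abs(grm.sum(axis=1)).max() < 1e-8
        assert np.allclose(grm, grm.T)
        assert np.linalg.eigvalsh(grm).min() > -1e-8
        # naive double-loop oracle over genotype pairs
        p = (X.mean(axis=0) + 1) / 2
        c = 2 * np.sum(p * (1 - p))
        M = X + 1 - 2 * p
        oracle = np.empty((20, 20))
        for i in range(20):
            for j in range(20):
                oracle[i, j] = np.dot(M[i], M[j]) / c
        assert np.abs(grm - oracle).max() < 1e-10

    def test_duplicated_genotype_rows_equal(self):
        rng = np.random.default_rng(7)
        X = rng.choice([-1.0, 1.0], size=(5, 30))
        X[1] = X[0]
        grm = compute_grm(mm(X)).values.to_numpy()
        assert np.allclose(grm[0], grm[1])

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(InputError):
            compute_grm(mm(np.ones((4, 5))))


class TestImputation:
    def test_duplicate_marker_fully_recovered(self):
        rng = np.random.default_rng(8)
        a = rng.choice([-1.0, 1.0], 120)
        X = pd.DataFrame({
            "focal": a.copy(), "twin": a.copy(),
            **{f"noise{i}": rng.choice([-1.0, 1.0], 120) for i in range(5)},
        })
        masked = rng.choice(120, size=12, replace=False)
        X.iloc[masked, 0] = np.nan
        out, report = impute_markers(MarkerMatrix(X), seed=0)
        assert report.loc["focal", "imputed"]
        assert np.allclose(out.calls["focal"].iloc[masked], a[masked])

    def test_linkage_free_marker_not_imputed(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({f"m{i}": rng.choice([-1.0, 1.0], 150) for i in range(12)})
        masked = rng.choice(150, size=15, replace=False)
        X.iloc[masked, 0] = np.nan
        out, report = impute_markers(MarkerMatrix(X), seed=0)
        assert not report.loc["m0", "imputed"]
        assert report.loc["m0", "oob_error"] >= 0.2
        assert out.calls["m0"].isna().sum() == 15

    def test_beats_majority_baseline_on_ld_panel(self, clean_genetics_config):
        from metfa.rng import stream
        from metfa.sim import simulate_genotypes
        mkm, _ = simulate_genotypes(clean_genetics_config)
        X = mkm.calls.to_numpy().copy()
        rng = stream(0, "mask-baseline")
        mask = rng.random(X.shape) < 0.10
        Xm = X.copy()
        Xm[mask] = np.nan
        out, _ = impute_markers(
            MarkerMatrix(pd.DataFrame(Xm, index=mkm.calls.index,
                                      columns=mkm.calls.columns)), seed=0)
        got = out.calls.to_numpy()
        filled = mask & ~np.isnan(got)
        acc = (got[filled] == X[filled]).mean()
        # majority-call baseline per marker
        maj_acc = []
        for j in range(X.shape[1]):
            col_mask = mask[:, j]
            if not col_mask.any():
                continue
            vals, counts = np.unique(X[~col_mask, j], return_counts=True)
            maj = vals[np.argmax(counts)]
            maj_acc.extend(X[col_mask, j] == maj)
        assert acc > np.mean(maj_acc)


def test_marker_pipeline_idempotent_on_own_output():
    """impute -> filter -> prune applied to its own output is a no-op."""
    from metfa.config import GeneticsConfig, SimulationConfig
    from metfa.sim import simulate_genotypes

    cfg = SimulationConfig(seed=4, genetics=GeneticsConfig(n_lines=60, n_markers=50))
    mk, _ = simulate_genotypes(cfg)

    def pipe(m):
        m1, _ = impute_markers(m, seed=0)
        m2 = filter_markers(m1)
        m3, _ = prune_markers(m2)
        return m3

    once = pipe(mk)
    twice = pipe(once)
    assert list(once.calls.columns) == list(twice.calls.columns)
    assert once.calls.fillna(9).equals(twice.calls.fillna(9))


class TestPurdy:
    def test_single_cross_has_seven_selfing_generations(self):
        ped = parse_purdy({"LINE1": "A/B"})
        tab = ped.table
        f1 = tab[(tab.p1 == "A") & (tab.p2 == "B")]
        assert len(f1) == 1
        # path from the F1 to the named line: 7 selfing steps
        child = {row.p1: row.id for row in tab.itertuples() if row.p1 == row.p2}
        steps, cur = 0, f1["id"].iloc[0]
        while cur in child:
            cur = child[cur]
            steps += 1
        assert steps == 7 and cur == "LINE1"

    def test_backcross_mates_f1_without_inbreeding(self):
        ped = parse_purdy({"BC1": "A/B//A"})
        tab = ped.table
        f1 = tab[(tab.p1 == "A") & (tab.p2 == "B")]["id"].iloc[0]
        top_cross = tab[(tab.p1 == f1) & (tab.p2 == "A")]
        assert len(top_cross) == 1  # F1 used directly, no selfing chain between

    def test_three_way_cross_selfs_intermediate(self):
        ped = parse_purdy({"TW": "A/B//C"})
        tab = ped.table
        f1 = tab[(tab.p1 == "A") & (tab.p2 == "B")]["id"].iloc[0]
        # the (A/B) product is selfed 7 generations before meeting C
        selfings = [r.id for r in tab.itertuples() if r.p1 == r.p2 and r.p1 is not None
                    and str(r.id).startswith(f"{f1}|S")]
        assert len(selfings) == 7
        top = tab[tab.p2 == "C"]
        assert len(top) == 1 and top["p1"].iloc[0] == selfings[-1]

    def test_nested_depth_ordering(self):
        ped = parse_purdy({"NEST": "A/B//C/3/D"})
        tab = ped.table
        # the /3/ cross is the outermost: its right parent is founder D
        assert (tab.p2 == "D").sum() == 1
        assert {"A", "B", "C", "D"} <= set(tab[tab.p1.isna()].id if "p1" in tab else [])\
            or {"A", "B", "C", "D"} <= set(tab.loc[tab.p1.isnull(), "id"])

    def test_star_backcross_count(self):
        ped = parse_purdy({"BC2": "A*3/B"})
        tab = ped.table
        # two extra backcross matings to A after the F1
        bc = tab[tab.p2 == "A"]
        assert len(bc) == 2

    def test_malformed_string_raises(self):
        with pytest.raises(PedigreeError):
            parse_purdy({"BAD": "A//B///"})

    def test_roundtrip_simulated_pedigrees(self, small_config):
        from metfa.sim import simulate_genotypes
        _, ped = simulate_genotypes(small_config)
        table = parse_purdy(dict(zip(ped["id"], ped["purdy"])))
        assert set(ped["id"]) <= set(table.ids)


class TestCOP:
    def test_unrelated_founders(self):
        ped = parse_purdy({"L1": "A/B", "L2": "C/D"})
        cop = compute_cop(ped)
        assert cop.values.loc["A", "A"] == 0.5
        assert cop.values.loc["A", "C"] == 0.0
        assert cop.values.loc["L1", "L2"] == 0.0

    def test_seven_generation_selfed_self_kinship(self):
        ped = parse_purdy({"L1": "A/B"})
        cop = compute_cop(ped)
        assert cop.values.loc["L1", "L1"] == pytest.approx(0.99609375, abs=1e-12)

    def test_full_sib_and_inbred_parent_kinship_oracle(self):
        # recursive oracle cases: full sibs from unrelated non-inbred parents
        # have kinship 1/4; from fully inbred parents, 1/2
        tab = pd.DataFrame({
            "id": ["A", "B", "S1", "S2"],
            "p1": [None, None, "A", "A"],
            "p2": [None, None, "B", "B"],
        })
        from metfa.genetics import PedigreeTable
        cop = compute_cop(PedigreeTable(tab))
        assert cop.values.loc["S1", "S2"] == pytest.approx(0.25)
        # fully inbred parents: phi(A,A) = phi(B,B) = 1
        tab2 = pd.DataFrame({
            "id": ["A0", "B0"] + [f"A{i}" for i in range(1, 30)] + [f"B{i}" for i in range(1, 30)] + ["S1", "S2"],
            "p1": [None, None] + [f"A{i-1}" for i in range(1, 30)] + [f"B{i-1}" for i in range(1, 30)] + ["A29", "A29"],
            "p2": [None, None] + [f"A{i-1}" for i in range(1, 30)] + [f"B{i-1}" for i in range(1, 30)] + ["B29", "B29"],
        })
        cop2 = compute_cop(PedigreeTable(tab2))
        assert cop2.values.loc["S1", "S2"] == pytest.approx(0.5, abs=1e-6)

    def test_cop_psd_and_stable_under_additions(self, small_config):
        from metfa.sim import simulate_genotypes
        _, ped = simulate_genotypes(small_config)
        strings = dict(zip(ped["id"], ped["purdy"]))
        sub = dict(list(strings.items())[:10])
        cop_small = compute_cop(parse_purdy(sub))
        cop_full = compute_cop(parse_purdy(strings))
        shared = [i for i in cop_small.ids if i in cop_full.ids]
        assert np.allclose(cop_small.values.loc[shared, shared],
                           cop_full.values.loc[shared, shared], atol=1e-12)
        assert np.linalg.eigvalsh(cop_full.values.to_numpy()).min() > -1e-8

    def test_cycle_detected(self):
        from metfa.genetics import PedigreeTable
        tab = pd.DataFrame({"id": ["X"], "p1": ["X"], "p2": ["X"]})
        with pytest.raises(PedigreeError):
            PedigreeTable(tab)
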