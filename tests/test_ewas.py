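from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossclock.ewas import (
    EwasResult,
    correlation_screen,
    overlap_counts,
    sector_classify,
    select_top_cpgs,
    stouffer_meta,
    zscore_concordance,
)

from .conftest import make_matrix, make_sheet


def screen(values, ages, **kwargs):
    return correlation_screen(make_matrix(values), make_sheet(ages), **kwargs)


class TestCorrelationScreen:
    def test_pearson_value(self):
        res = screen([[0.1, 0.2, 0.4, 0.3]], [1.0, 2.0, 4.0, 3.0])
        assert res.table["r"].iloc[0] == pytest.approx(1.0)
        res = screen([[0.1, 0.2, 0.4, 0.35]], [1.0, 2.0, 4.0, 3.0])
        # direct formula on the same numbers
        expected = stats.pearsonr([0.1, 0.2, 0.4, 0.35], [1, 2, 4, 3])
        assert res.table["r"].iloc[0] == pytest.approx(expected[0], abs=1e-12)
        assert res.table["p"].iloc[0] == pytest.approx(expected[1], rel=1e-9)

    def test_constant_probe_invalid(self):
        res = screen([[0.5, 0.5, 0.5, 0.5]], [1.0, 2.0, 3.0, 4.0])
        row = res.table.iloc[0]
        assert not row["valid"] and row["r"] == 0 and row["p"] == 1 and row["z"] == 0

    def test_age_negation_flips_sign(self):
        rng = np.random.default_rng(0)
        values = rng.random((20, 8))
        ages = np.linspace(0.1, 3.0, 8)
        a = screen(values, ages)
        b = correlation_screen(make_matrix(values), make_sheet(ages), age=-ages)
        np.testing.assert_allclose(b.table["r"], -a.table["r"], atol=1e-12)
        np.testing.assert_allclose(b.table["z"], -a.table["z"], atol=1e-9)
        np.testing.assert_allclose(b.table["p"], a.table["p"], atol=1e-12)

    def test_pairwise_complete_counts(self):
        values = np.array([[0.1, np.nan, 0.3, 0.4, 0.5]])
        res = screen(values, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.table["n_used"].iloc[0] == 4

    def test_fisher_z_definition(self):
        rng = np.random.default_rng(1)
        values = rng.random((5, 10))
        ages = np.linspace(0, 3, 10)
        res = screen(values, ages)
        r = res.table["r"].to_numpy()
        np.testing.assert_allclose(
            res.table["z"], np.arctanh(r) * np.sqrt(10 - 3), atol=1e-9
        )

    def test_mixed_stratum_rejected(self):
        matrix = make_matrix(np.random.default_rng(0).random((3, 4)))
        sheet = make_sheet([1, 2, 3, 4])
        sheet.samples.loc[0, "tissue"] = "liver"
        with pytest.raises(ValueError, match="one species and one tissue"):
            correlation_screen(matrix, sheet)

    def test_p_matches_permutation_null(self):
        """Student-t p agrees with a 10^5-draw permutation p on one probe."""
        rng = np.random.default_rng(2)
        beta = rng.random(10)
        ages = np.linspace(0.2, 3.4, 10)
        res = screen(beta[None, :], ages)
        p_t = res.table["p"].iloc[0]
        r_obs = abs(res.table["r"].iloc[0])
        n_perm = 100_000
        perms = np.array([rng.permutation(beta) for _ in range(n_perm)])
        pc = (perms - perms.mean(1, keepdims=True)) / perms.std(1, keepdims=True)
        ac = (ages - ages.mean()) / ages.std()
        r_perm = pc @ ac / len(ages)
        p_perm = (np.abs(r_perm) >= r_obs - 1e-12).mean()
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_t - p_perm) < 4 * se + 0.005


class TestStouffer:
    def _result(self, z, n, stratum=("sp", "t0"), probe_ids=None):
        z = np.asarray(z, dtype=float)
        probe_ids = probe_ids or [f"cg{i:03d}" for i in range(len(z))]
        return EwasResult(
            stratum=stratum,
            table=pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "n_used": n,
                    "r": np.tanh(z / np.sqrt(max(n - 3, 1))),
                    "z": z,
                    "p": 2 * stats.norm.sf(np.abs(z)),
                    "valid": True,
                }
            ),
        )

    def test_four_identical_strata(self):
        results = [self._result([1.0], 10, ("sp", f"t{i}")) for i in range(4)]
        meta = stouffer_meta(results, weights={("sp", f"t{i}"): 1.0 for i in range(4)})
        assert meta.table["z_meta"].iloc[0] == pytest.approx(2.0)

    def test_closed_form_weights(self):
        results = [
            self._result([2.0], 10, ("sp", "a")),
            self._result([0.0], 40, ("sp", "b")),
        ]
        meta = stouffer_meta(results)  # default weights sqrt(n)
        assert meta.table["z_meta"].iloc[0] == pytest.approx(
            2 * np.sqrt(10) / np.sqrt(50)
        )

    def test_single_stratum_identity(self):
        res = self._result([1.3, -0.2], 12)
        meta = stouffer_meta([res])
        np.testing.assert_allclose(meta.table["z_meta"], res.table["z"])
        np.testing.assert_allclose(
            meta.table["p_meta"], 2 * stats.norm.sf(np.abs(res.table["z"]))
        )

    def test_invariant_to_stratum_order(self):
        a = self._result([0.5, 1.5], 10, ("sp", "a"))
        b = self._result([-1.0, 2.0], 20, ("sp", "b"))
        m1 = stouffer_meta([a, b]).table
        m2 = stouffer_meta([b, a]).table.set_index("probe_id").loc[m1["probe_id"]]
        np.testing.assert_allclose(m1["z_meta"], m2["z_meta"].to_numpy())

    def test_invalid_probe_renormalized(self):
        a = self._result([1.0, 1.0], 10, ("sp", "a"))
        b = self._result([1.0, 1.0], 10, ("sp", "b"))
        b.table.loc[1, "valid"] = False
        meta = stouffer_meta([a, b]).table
        assert meta["k_strata"].tolist() == [2, 1]
        assert meta["z_meta"].iloc[1] == pytest.approx(1.0)

    def test_all_invalid_gives_null_record(self):
        a = self._result([1.0], 10)
        a.table["valid"] = False
        meta = stouffer_meta([a]).table
        assert meta["z_meta"].iloc[0] == 0.0 and meta["p_meta"].iloc[0] == 1.0


class TestSelectTop:
    def _result(self, z, p):
        n = len(z)
        return EwasResult(
            stratum=("sp", "t"),
            table=pd.DataFrame(
                {
                    "probe_id": [f"cg{i:03d}" for i in range(n)],
                    "n_used": 10, "r": 0.0, "z": z, "p": p, "valid": True,
                }
            ),
        )

    def test_up_to_semantics(self):
        z = [3, 2, 4, 1, -3, -2, 0.5, 0.2, 0.1, 0.05]
        p = [1e-6, 1e-5, 1e-7, 1e-4, 1e-6, 1e-5, 0.5, 0.6, 0.7, 0.8]
        up, down = select_top_cpgs(self._result(z, p), 500, p_threshold=1e-3)
        assert len(up) == 4 and len(down) == 2

    def test_tie_broken_by_abs_z(self):
        res = self._result([2.0, 3.0], [1e-5, 1e-5])
        up, _ = select_top_cpgs(res, 1, p_threshold=1e-3)
        assert up == ["cg001"]

    def test_k_smallest_p_selected(self):
        p = [5e-5, 1e-5, 3e-5, 2e-5, 4e-5]
        res = self._result([1.0] * 5, p)
        up, _ = select_top_cpgs(res, 3, p_threshold=1e-3)
        # brute-force oracle: sort indices by p
        expected = [f"cg{i:03d}" for i in np.argsort(p)[:3]]
        assert up == expected

    def test_idempotent_at_large_k(self):
        res = self._result([2, -2, 3], [1e-5, 1e-5, 0.5])
        up, down = select_top_cpgs(res, 10**6, p_threshold=1e-3)
        assert set(up) == {"cg000"} and set(down) == {"cg001"}


class TestOverlapCounts:
    def test_two_sets(self):
        out = overlap_counts({"A": [1, 2, 3], "B": [2, 3, 4]})
        assert out[frozenset({"A"})] == 1
        assert out[frozenset({"B"})] == 1
        assert out[frozenset({"A", "B"})] == 2

    def test_three_identical_sets(self):
        s = list(range(5))
        out = overlap_counts({"A": s, "B": s, "C": s})
        assert out[frozenset({"A", "B", "C"})] == 5
        assert sum(v for k, v in out.items() if len(k) < 3) == 0

    def test_against_membership_enumeration(self):
        rng = np.random.default_rng(3)
        sets = {
            name: set(rng.choice(40, size=rng.integers(5, 25), replace=False).tolist())
            for name in "ABCD"
        }
        out = overlap_counts(sets)
        union = set().union(*sets.values())
        assert sum(out.values()) == len(union)
        for element in union:
            member_of = frozenset(n for n, s in sets.items() if element in s)
            assert out[member_of] >= 1
        # exhaustive oracle per region
        for region, count in out.items():
            brute = sum(
                1
                for e in union
                if frozenset(n for n, s in sets.items() if e in s) == region
            )
            assert count == brute

    def test_limits_on_set_count(self):
        with pytest.raises(ValueError):
            overlap_counts({"A": [1]})
        with pytest.raises(ValueError):
            overlap_counts({k: [1] for k in "ABCDE"})


class TestSectorClassify:
    def classify(self, zx, zy, **kw):
        sc = sector_classify(
            np.atleast_1d(zx), np.atleast_1d(zy), ["cg0"], p_strict=1e-4, **kw
        )
        return sc.table["category"].iloc[0]

    def test_reference_cases(self):
        # z* for p=1e-4 two-sided is 3.8906
        assert self.classify(4.0, 4.0) == "shared_up"
        assert self.classify(-4.0, -4.0) == "shared_down"
        assert self.classify(4.0, -4.0) == "divergent"
        assert self.classify(4.0, 0.5) == "x_only"
        assert self.classify(0.5, 4.0) == "y_only"
        assert self.classify(0.5, 0.5) == "null"
        # beyond strict in x, between lenient and strict in y: neither
        assert self.classify(4.0, 3.0) == "null"

    def test_threshold_is_normal_quantile(self):
        z_star = stats.norm.isf(1e-4 / 2)
        assert self.classify(z_star + 1e-6, z_star + 1e-6) == "shared_up"
        assert self.classify(z_star - 1e-6, z_star - 1e-6) == "null"

    def test_exclusive_exhaustive(self):
        rng = np.random.default_rng(4)
        zx, zy = rng.normal(0, 3, 500), rng.normal(0, 3, 500)
        sc = sector_classify(zx, zy, [f"cg{i}" for i in range(500)], p_strict=1e-3)
        assert sc.table["category"].isin(
            ["shared_up", "shared_down", "divergent", "x_only", "y_only", "null"]
        ).all()

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            sector_classify([1.0], [1.0], ["cg0"], p_strict=0.5, p_lenient=0.05)


class TestZScoreConcordance:
    def test_exact_cases(self):
        z = np.array([0.2, -1.0, 2.0, 0.5])
        assert zscore_concordance(z, z)[0] == pytest.approx(1.0)
        assert zscore_concordance(z, -z)[0] == pytest.approx(-1.0)

    def test_degenerate_flagged(self):
        r, degenerate = zscore_concordance([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        assert r == 0.0 and degenerate

    def test_shared_signal_strata_concordant(self):
        """Two strata sharing half their age probes show clear z concordance."""
        from crossclock.synthetic_data import (
            SimulationConfig,
            SpeciesSpec,
            simulate_dataset,
        )

        cfg = SimulationConfig(
            species_specs=[SpeciesSpec("opossum", 4.2, 0.5, 25)],
            tissues=["ear", "liver"], n_probes=1000, frac_age_related=0.3,
            frac_shared_age=1.0, seed=13,
        )
        matrix, sheet, _, _ = simulate_dataset(cfg)
        res = {}
        for tissue in ("ear", "liver"):
            sub = sheet.subset((sheet.samples["tissue"] == tissue).to_numpy())
            res[tissue] = correlation_screen(matrix, sub)
        r, _ = zscore_concordance(res["ear"].table["z"], res["liver"].table["z"])
        assert r > 0.3
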