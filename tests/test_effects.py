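import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sharplight.cluster import Cluster, ClusterSet
from sharplight.effects import (
    extract_cluster_means,
    paired_t,
    rm_anova,
    within_subject_ci,
)


def brute_force_rm_anova(table, factors, subject="subject_id", value="value"):
    """Independent SS decomposition via explicit cell-mean loops.

    Deliberately different code path from the implementation: builds every
    marginal mean with pandas groupby and accumulates squared deviations
    cell by cell.
    """
    subjects = sorted(table[subject].unique())
    levels = {f: sorted(table[f].unique()) for f in factors}
    grand = table[value].mean()

    def marginal(cols):
        if not cols:
            return lambda _key: grand
        means = table.groupby(list(cols))[value].mean()
        return lambda key: means[key if len(key) > 1 else key[0]]

    out = {}
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            # effect term per cell via inclusion-exclusion over subsets
            def term(key, cols):
                tot = 0.0
                for rr in range(len(cols) + 1):
                    for sub in itertools.combinations(range(len(cols)), rr):
                        m = marginal(tuple(cols[i] for i in sub))
                        tot += ((-1) ** (len(cols) - rr)) * m(tuple(key[i] for i in sub))
                return tot

            n_rest = len(table) / np.prod([len(levels[f]) for f in combo])
            ss = 0.0
            for key in itertools.product(*(levels[f] for f in combo)):
                ss += n_rest * term(key, combo) ** 2
            # error: same construction with subject appended as a factor
            cols_err = (subject, *combo)
            lev_err = [subjects] + [levels[f] for f in combo]
            n_rest_err = len(table) / np.prod([len(l) for l in lev_err])
            ss_err = 0.0
            for key in itertools.product(*lev_err):
                ss_err += n_rest_err * term(key, cols_err) ** 2
            df_num = int(np.prod([len(levels[f]) - 1 for f in combo]))
            df_den = df_num * (len(subjects) - 1)
            F = (ss / df_num) / (ss_err / df_den)
            out[" x ".join(combo)] = dict(ss=ss, ss_error=ss_err, F=F, df_num=df_num, df_den=df_den)
    return out


def random_table(rng, n_sub, level_spec):
    rows = []
    for s in range(n_sub):
        for combo in itertools.product(*(range(k) for k in level_spec.values())):
            rows.append(
                {
                    "subject_id": f"s{s}",
                    **{f: f"{f}{v}" for f, v in zip(level_spec, combo)},
                    "value": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestRmAnova:
    @pytest.mark.parametrize(
        "level_spec",
        [{"fa": 2, "fb": 2}, {"fa": 2, "fb": 3}, {"fa": 3, "fb": 2, "fc": 2}],
    )
    def test_matches_brute_force_oracle(self, rng, level_spec):
        table = random_table(rng, 5, level_spec)
        res = rm_anova(table, list(level_spec))
        oracle = brute_force_rm_anova(table, list(level_spec))
        for name, o in oracle.items():
            row = res.effect(name)
            assert row["F"] == pytest.approx(o["F"], abs=1e-10)
            assert row["ss"] == pytest.approx(o["ss"], abs=1e-10)
            assert (row["df_num"], row["df_den"]) == (o["df_num"], o["df_den"])

    def test_matches_statsmodels_anovarm(self, rng):
        sm = pytest.importorskip("statsmodels.stats.anova")
        table = random_table(rng, 6, {"fa": 2, "fb": 3})
        res = rm_anova(table, ["fa", "fb"])
        ref = sm.AnovaRM(table, "value", "subject_id", within=["fa", "fb"]).fit().anova_table
        for ours, theirs in [("fa", "fa"), ("fb", "fb"), ("fa x fb", "fa:fb")]:
            assert res.effect(ours)["F"] == pytest.approx(ref.loc[theirs, "F Value"], rel=1e-9)

    def test_two_level_factor_F_equals_squared_paired_t(self, rng):
        table = random_table(rng, 8, {"fa": 2})
        res = rm_anova(table, ["fa"])
        wide = table.pivot_table(index="subject_id", columns="fa", values="value")
        t = paired_t(wide["fa0"].to_numpy(), wide["fa1"].to_numpy())
        assert res.effect("fa")["F"] == pytest.approx(t.t**2, rel=1e-12)
        assert res.effect("fa")["p"] == pytest.approx(t.p, rel=1e-12)

    def test_constant_conditions_give_zero_F(self):
        rows = [
            {"subject_id": f"s{s}", "fa": a, "value": float(s)}
            for s in range(4)
            for a in ("x", "y")
        ]
        res = rm_anova(pd.DataFrame(rows), ["fa"])
        assert res.effect("fa")["F"] == 0.0

    def test_ss_decomposition_is_exact(self, rng):
        res = rm_anova(random_table(rng, 4, {"fa": 2, "fb": 2}), ["fa", "fb"])
        total = res.table["ss"].sum() + res.table["ss_error"].sum() + res.ss_subject
        assert total == pytest.approx(res.ss_total, abs=1e-10)

    def test_missing_cells_are_listed(self, rng):
        table = random_table(rng, 4, {"fa": 2, "fb": 2})
        broken = table.drop(table.index[3])
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova(broken, ["fa", "fb"])

    def test_partial_eta_sq_matches_definition(self, rng):
        res = rm_anova(random_table(rng, 5, {"fa": 2, "fb": 2}), ["fa", "fb"])
        for _, row in res.table.iterrows():
            assert row["partial_eta_sq"] == pytest.approx(row["ss"] / (row["ss"] + row["ss_error"]))


class TestPairedT:
    def test_hand_computed_value(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_t(x, np.zeros(3))
        assert res.t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-12)
        assert res.df == 2

    def test_identical_inputs(self):
        res = paired_t(np.ones(5), np.ones(5))
        assert res.t == 0.0 and res.p == 1.0

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert paired_t(x, y).t == pytest.approx(-paired_t(y, x).t, rel=1e-12)

    def test_zero_variance_nonzero_mean_flagged_infinite(self):
        res = paired_t(np.array([1.0, 1.0, 1.0]), np.zeros(3))
        assert np.isinf(res.t) and res.degenerate


class TestWithinSubjectCI:
    def test_closed_form_half_width(self, rng):
        """n = 20 and difference SD 0.1 give t₀.₉₇₅,₁₉ · 0.1/√20 ÷ √2."""
        n = 20
        base = rng.normal(size=n)
        d = rng.normal(size=n)
        d = (d - d.mean()) / d.std(ddof=1) * 0.1  # exact SD 0.1
        rows = []
        for i in range(n):
            rows.append({"subject_id": i, "congruency": "congruent", "value": base[i] + d[i]})
            rows.append({"subject_id": i, "congruency": "incongruent", "value": base[i]})
        out = within_subject_ci(pd.DataFrame(rows), "congruency")
        expected = stats.t.ppf(0.975, n - 1) * 0.1 / np.sqrt(n) / np.sqrt(2)
        assert out["ci_half_width"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.0331, abs=5e-4)

    def test_identical_conditions_zero_width(self):
        rows = [
            {"subject_id": i, "congruency": c, "value": float(i)}
            for i in range(5)
            for c in ("congruent", "incongruent")
        ]
        out = within_subject_ci(pd.DataFrame(rows), "congruency")
        assert out["ci_half_width"].iloc[0] == 0.0

    def test_scaling_homogeneity(self, rng):
        rows = [
            {"subject_id": i, "congruency": c, "value": float(rng.normal())}
            for i in range(6)
            for c in ("congruent", "incongruent")
        ]
        t1 = pd.DataFrame(rows)
        t2 = t1.assign(value=t1["value"] * -3.0)
        a = within_subject_ci(t1, "congruency")["ci_half_width"].iloc[0]
        b = within_subject_ci(t2, "congruency")["ci_half_width"].iloc[0]
        assert b == pytest.approx(3.0 * a, rel=1e-12)

    def test_more_than_two_levels_rejected(self):
        rows = [
            {"subject_id": i, "cond": c, "value": 0.0}
            for i in range(3)
            for c in ("a", "b", "c")
        ]
        with pytest.raises(ValueError, match="2-level"):
            within_subject_ci(pd.DataFrame(rows), "cond")


class TestExtractClusterMeans:
    def _rois(self):
        return ClusterSet(
            clusters=[
                Cluster("c1", [(0, 0, 0)], 1, 5.0),
                Cluster("c2", [(1, 0, 0), (1, 1, 0)], 2, 4.0),
            ]
        )

    def test_means_and_crossing(self):
        vol_a = np.zeros((2, 2, 2))
        vol_a[0, 0, 0] = 0.3
        vol_a[1, 0, 0], vol_a[1, 1, 0] = 0.10, 0.20
        volumes = {"s1": {("congruent",): vol_a, ("incongruent",): vol_a * 2}}
        table = extract_cluster_means(volumes, self._rois(), ["congruency"])
        assert len(table) == 1 * 2 * 2  # subjects × clusters × cells
        c1 = table[(table["cluster"] == "c1") & (table["congruency"] == "congruent")]
        assert c1["value"].iloc[0] == pytest.approx(0.3)
        c2 = table[(table["cluster"] == "c2") & (table["congruency"] == "congruent")]
        assert c2["value"].iloc[0] == pytest.approx(0.15)

    def test_voxel_outside_mask_rejected(self):
        vol = np.full((2, 2, 2), np.nan)
        with pytest.raises(ValueError, match="outside the valid mask"):
            extract_cluster_means({"s1": {("congruent",): vol}}, self._rois(), ["congruency"])
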