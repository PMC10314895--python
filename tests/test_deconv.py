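import numpy as np
import pandas as pd
import pytest

from degradomap import deconv, simgen
from degradomap.deconv import HitSet, HitThresholds


def make_diff(log2fc, q, status=None, proteins=None):
    log2fc = np.asarray(log2fc, float)
    q = np.asarray(q, float)
    proteins = proteins or [f"P{i}" for i in range(len(log2fc))]
    return pd.DataFrame(
        {"log2fc": log2fc, "q": q,
         "status": status or ["ok"] * len(log2fc)},
        index=pd.Index(proteins, name="protein_id"),
    )


def make_hits(entries, contrast="c", thresholds=HitThresholds()):
    """entries: {protein: (log2fc, q)}"""
    table = pd.DataFrame(
        {"log2fc": [v[0] for v in entries.values()],
         "q": [v[1] for v in entries.values()]},
        index=pd.Index(list(entries), name="protein_id"),
    )
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    table["tier"] = "primary"
    return HitSet(contrast=contrast, thresholds=thresholds, table=table)


class TestThresholds:
    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            HitThresholds(fc_min=1.0)
        with pytest.raises(ValueError):
            HitThresholds(q_max=0.0)

    def test_first_tier_cut_is_log2_of_fold_change(self):
        assert HitThresholds().log2fc_min == pytest.approx(np.log2(1.5))
        assert HitThresholds().log2fc_min == pytest.approx(0.5849625, abs=1e-6)

    def test_stringent_cut_equals_ten_to_minus_2p5(self):
        assert HitThresholds().stringent_q_max == pytest.approx(10**-2.5)
        assert HitThresholds().stringent_q_max == pytest.approx(3.1623e-3, rel=1e-4)


class TestCallArmHits:
    def test_downregulated_significant_protein_is_down_hit(self):
        diff = make_diff([-1.2], [0.002])
        hits = deconv.call_arm_hits(diff)
        assert list(hits.table.index) == ["P0"]
        assert hits.table.iloc[0]["direction"] == "down"

    @pytest.mark.parametrize("log2fc,q,is_hit", [
        (-1.2, 0.05, False),          # q boundary: strict
        (np.log2(1.5), 0.002, False), # fc boundary: strict
        (0.7, 0.049, True),
        (-0.5, 0.001, False),
    ])
    def test_strict_boundaries(self, log2fc, q, is_hit):
        hits = deconv.call_arm_hits(make_diff([log2fc], [q]))
        assert (len(hits) == 1) == is_hit

    def test_untested_excluded(self):
        diff = make_diff([-2.0, -2.0], [0.001, 0.001], status=["untested", "ok"])
        assert list(deconv.call_arm_hits(diff).table.index) == ["P1"]

    def test_matches_rowwise_enumeration_oracle(self, rng):
        diff = make_diff(rng.normal(0, 1.2, 200), rng.random(200))
        th = HitThresholds()
        hits = deconv.call_arm_hits(diff, th)
        for pid, row in diff.iterrows():
            expected = abs(row["log2fc"]) > np.log2(1.5) and row["q"] < 0.05
            assert (pid in hits.proteins) == expected

    def test_monotone_in_thresholds(self, rng):
        diff = make_diff(rng.normal(0, 1.2, 300), rng.random(300))
        loose = deconv.call_arm_hits(diff, HitThresholds(fc_min=1.3, q_max=0.1))
        tight = deconv.call_arm_hits(diff, HitThresholds(fc_min=2.0, q_max=0.01))
        assert tight.proteins <= loose.proteins


class TestExclusiveHits:
    def test_empty_controls_identity(self):
        t = make_hits({"a": (-2, 0.01), "b": (1, 0.02)})
        assert deconv.exclusive_hits(t, []).proteins == {"a", "b"}

    def test_superset_controls_empty(self):
        t = make_hits({"a": (-2, 0.01)})
        c = make_hits({"a": (-2, 0.01), "b": (1, 0.02)})
        assert deconv.exclusive_hits(t, [c]).proteins == set()

    def test_matches_set_difference_oracle(self, rng):
        names = [f"P{i}" for i in range(40)]
        def random_hits():
            chosen = [n for n in names if rng.random() < 0.4]
            return make_hits({n: (rng.normal(), rng.random() * 0.05) for n in chosen}
                             or {"Q": (-2, 0.01)})
        t, c1, c2 = random_hits(), random_hits(), random_hits()
        out = deconv.exclusive_hits(t, [c1, c2])
        assert out.proteins == t.proteins - (c1.proteins | c2.proteins)


class TestIntersectReplicates:
    def test_identity(self):
        h = make_hits({"a": (-2, 0.01), "b": (1, 0.02)})
        assert deconv.intersect_replicates(h, h).proteins == {"a", "b"}

    def test_direction_mismatch_excluded_and_logged(self):
        a = make_hits({"a": (-2, 0.01), "b": (1, 0.02)})
        b = make_hits({"a": (2, 0.01), "b": (1, 0.02)})
        out = deconv.intersect_replicates(a, b)
        assert out.proteins == {"b"}
        assert out.table.attrs["direction_mismatch"] == ["a"]

    def test_matches_set_intersection_oracle(self, rng):
        names = [f"P{i}" for i in range(30)]
        a = make_hits({n: (abs(rng.normal()) + 1, 0.01) for n in names if rng.random() < 0.5}
                      or {"X": (1, 0.01)})
        b = make_hits({n: (abs(rng.normal()) + 1, 0.01) for n in names if rng.random() < 0.5}
                      or {"X": (1, 0.01)})
        assert deconv.intersect_replicates(a, b).proteins == a.proteins & b.proteins


class TestStringentFilter:
    def test_strong_downregulation_passes(self):
        diff = make_diff([-1.5], [0.001], proteins=["a"])
        shared = make_hits({"a": (-1.5, 0.001)})
        out = deconv.stringent_filter(diff, shared)
        assert out.proteins == {"a"} and out.table.iloc[0]["tier"] == "stringent"

    def test_boundary_log2fc_fails_strictly(self):
        diff = make_diff([-1.0], [0.0001], proteins=["a"])
        shared = make_hits({"a": (-1.0, 0.0001)})
        assert deconv.stringent_filter(diff, shared).proteins == set()

    def test_q_cut_equivalent_to_neglog10_form(self, rng):
        qs = 10 ** rng.uniform(-4, -1, 100)
        diff = make_diff([-2.0] * 100, qs)
        shared = make_hits({f"P{i}": (-2.0, qs[i]) for i in range(100)})
        out = deconv.stringent_filter(diff, shared)
        for i, q in enumerate(qs):
            assert (f"P{i}" in out.proteins) == (-np.log10(q) > 2.5)
            assert (f"P{i}" in out.proteins) == (q < 10**-2.5)

    def test_upregulated_never_stringent(self):
        diff = make_diff([2.0], [1e-5], proteins=["a"])
        shared = make_hits({"a": (2.0, 1e-5)})
        assert deconv.stringent_filter(diff, shared).proteins == set()


class TestVolcanoTable:
    def test_coordinates_and_cap(self):
        diff = make_diff([-1.0, 2.0], [0.01, 0.0])
        out = deconv.volcano_table(diff)
        assert out.loc["P0", "neglog10_q"] == pytest.approx(2.0)
        assert out.loc["P1", "neglog10_q"] == 300.0

    def test_row_count_equals_tested(self):
        diff = make_diff([-1, 1, 0], [0.1, 0.2, 0.3],
                         status=["ok", "untested", "ok"])
        assert len(deconv.volcano_table(diff)) == 2


class TestFunnelNesting:
    def test_stringent_within_shared_within_exclusive(self):
        cfg = simgen.SimProteomeConfig(
            n_proteins=800, n_direct_targets=3, n_shared_pharmacology=6,
            n_neosubstrates=3, seed=23)
        exp_a, exp_b, _ = simgen.simulate_replicate_pair(cfg, 0.8)
        res = deconv.deconvolution_funnel([exp_a, exp_b])
        excl_a = res["per_experiment"][0]["exclusive"].proteins
        excl_b = res["per_experiment"][1]["exclusive"].proteins
        shared = res["shared"].proteins
        stringent = res["stringent"].proteins
        assert stringent <= shared <= excl_a
        assert shared <= excl_b
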