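import numpy as np
import pandas as pd
import pytest

from poolscreen import fitness as fit
from poolscreen import pipeline as pl
from poolscreen import strain_calling as sc
from poolscreen import synthetic_pool as sp
from poolscreen.errors import ConfigurationError


def make_cons(cols: dict) -> pd.DataFrame:
    """Consensus-level (3-level) fitness table from literal values."""
    df = pd.DataFrame({k: pd.Series(v) for k, v in cols.items()})
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["pretreatment", "comparison", "replicate"]
    )
    return df


def brute_force_stringent(cons, pretreatment, z_threshold=1.0,
                          min_replicates=2):
    """Literal per-strain re-evaluation of the calling criteria."""
    reps = sorted({r for (p, c, r) in cons.columns
                   if p == pretreatment and c == "S4vS3"})
    called = set()
    for strain in cons.index:
        n = 0
        for rep in reps:
            f4 = cons[(pretreatment, "S4vS3", rep)][strain]
            f3 = cons[(pretreatment, "S3vS1", rep)][strain]
            f2 = cons[(pretreatment, "S2vS1", rep)][strain]
            if np.isnan(f4) or np.isnan(f3) or np.isnan(f2):
                continue
            col4 = cons[(pretreatment, "S4vS3", rep)].dropna()
            col3 = cons[(pretreatment, "S3vS1", rep)].dropna()
            z4 = (f4 - col4.mean()) / col4.std(ddof=0)
            z3 = (f3 - col3.mean()) / col3.std(ddof=0)
            if z4 <= -z_threshold and z3 > -z_threshold and f2 > f4:
                n += 1
        if n >= min_replicates:
            called.add(strain)
    return called


NULLS = {f"n{i}": v for i, v in enumerate(
    [0.2, -0.2, 0.3, -0.3, 0.1, -0.1, 0.25, -0.25]
)}


def basic_table(hit_f4=-2.0, hit_f3=0.0, hit_f2=-0.1, reps=(1, 2),
                hit="hit"):
    cols = {}
    for rep in reps:
        cols[("NaCl", "S4vS3", rep)] = {**NULLS, hit: hit_f4}
        cols[("NaCl", "S3vS1", rep)] = {**NULLS, hit: hit_f3}
        cols[("NaCl", "S2vS1", rep)] = {**NULLS, hit: hit_f2}
    return make_cons(cols)


class TestCallStringent:
    def test_textbook_hit_called(self):
        cons = basic_table()
        calls = sc.call_stringent(cons, "NaCl")
        assert calls.called == {"hit"}
        audit = calls.audit["hit"]
        assert audit.route == "stringent"
        assert audit.n_replicates_passing == 2
        assert calls.called == brute_force_stringent(cons, "NaCl")

    def test_pretreatment_sensitive_not_called(self):
        # fails criterion 2 in both replicates
        cons = basic_table(hit_f3=-3.0)
        calls = sc.call_stringent(cons, "NaCl")
        assert calls.called == set()
        assert not calls.audit["hit"].crit2_pass
        assert calls.audit["hit"].crit1_pass

    def test_equal_lowdose_defect_not_called(self):
        # criterion 3 requires strictly smaller low-dose defect; tie excludes
        cons = basic_table(hit_f2=-2.0, hit_f4=-2.0)
        assert sc.call_stringent(cons, "NaCl").called == set()

    def test_one_of_three_replicates_not_called(self):
        cols = {}
        for rep in (1, 2, 3):
            f4 = -2.0 if rep == 1 else 0.05
            cols[("NaCl", "S4vS3", rep)] = {**NULLS, "hit": f4}
            cols[("NaCl", "S3vS1", rep)] = {**NULLS, "hit": 0.0}
            cols[("NaCl", "S2vS1", rep)] = {**NULLS, "hit": -0.1}
        cons = make_cons(cols)
        calls = sc.call_stringent(cons, "NaCl")
        assert calls.called == set()
        assert calls.audit["hit"].n_replicates_passing == 1

    def test_missing_comparison_raises(self):
        cons = make_cons({("NaCl", "S4vS3", 1): {**NULLS, "hit": -2.0}})
        with pytest.raises(ConfigurationError, match="S3vS1"):
            sc.call_stringent(cons, "NaCl", min_replicates=1)

    def test_accepts_four_level_table(self):
        cols = {
            fit.Comparison("NaCl", comp, rep, platform): vals
            for (pre, comp, rep), vals in basic_table().to_dict().items()
            for platform in ("UP", "DN")
        }
        table = fit.build_table(cols)
        assert sc.call_stringent(table, "NaCl").called == {"hit"}

    def test_matches_bruteforce_on_noisy_screen(self):
        cat = sp.make_catalog(80, seed=31)
        pl.plant_defects(cat, ["NaCl"], seed=32, n_acquired=10,
                         acquired_survival=0.3, n_pretreat_sensitive=5,
                         n_uniform_sensitive=5)
        table = pl.run_screen(cat, ["NaCl"], n_replicates=2, depth=30_000,
                              error_rate=0.01, seed=33)
        cons = fit.consensus(table)
        calls = sc.call_stringent(table, "NaCl")
        assert calls.called == brute_force_stringent(cons, "NaCl")


class TestExpandByCorrelation:
    def test_identical_profile_added(self):
        cons = basic_table()
        # candidate matches the hit but lacks rep-2 severe data, so it
        # cannot be called stringently (needs two passing replicates)
        for comp in ("S4vS3", "S3vS1", "S2vS1"):
            for rep in (1, 2):
                cons.loc["cand", ("NaCl", comp, rep)] = cons[
                    ("NaCl", comp, rep)]["hit"]
        cons.loc["cand", ("NaCl", "S4vS3", 2)] = np.nan
        stringent = sc.call_stringent(cons, "NaCl")
        assert stringent.called == {"hit"}
        expanded = sc.expand_by_correlation(stringent, cons, r_min=0.9)
        assert "cand" in expanded.called
        assert expanded.audit["cand"].added_by_correlation

    def test_guard_blocks_weak_severe_phenotype(self):
        cons = basic_table()
        # highly correlated profile but z(S4vS3) > -1 in every replicate
        for rep in (1, 2):
            cons.loc["weak", ("NaCl", "S4vS3", rep)] = -0.4
            cons.loc["weak", ("NaCl", "S3vS1", rep)] = 0.0
            cons.loc["weak", ("NaCl", "S2vS1", rep)] = -0.1
        from poolscreen.set_analysis import uncentered_pearson

        vecs = sc.uncentered_correlation_candidates(cons, "NaCl")
        r = uncentered_pearson(vecs.loc["weak"].to_numpy(),
                               vecs.loc["hit"].to_numpy())
        assert r >= 0.9  # precondition: the correlation alone would add it
        crit = sc.criteria_frame(cons, "NaCl")
        assert not any(crit[(rep, "c1")]["weak"] for rep in (1, 2))
        expanded = sc.expand_by_correlation(
            sc.call_stringent(cons, "NaCl"), cons, r_min=0.9)
        assert "weak" not in expanded.called

    def test_empty_stringent_set_noop(self):
        cons = basic_table(hit_f4=0.0)
        stringent = sc.call_stringent(cons, "NaCl")
        assert stringent.called == set()
        expanded = sc.expand_by_correlation(stringent, cons)
        assert expanded.called == set()

    def test_invalid_r_min(self):
        cons = basic_table()
        with pytest.raises(ValueError):
            sc.expand_by_correlation(sc.call_stringent(cons, "NaCl"),
                                     cons, r_min=1.5)


class TestCallSingleReplicate:
    @staticmethod
    def single_rep_table():
        strains = {
            # passes both severe doses
            "het_two_dose": dict(f4=-2.0, f4a=-2.2, f3=0.0, f2=-0.1),
            # passes 1.0 mM only
            "het_one_dose": dict(f4=-2.0, f4a=0.1, f3=0.0, f2=-0.1),
            # passes 1.0 mM only, but the damp mutant of the same gene passes
            "het_shared": dict(f4=-2.1, f4a=0.0, f3=0.0, f2=-0.1),
            "damp_shared": dict(f4=-2.3, f4a=0.0, f3=0.0, f2=-0.1),
        }
        cols = {
            ("NaCl", "S4vS3", 1): {**NULLS},
            ("NaCl", "S4AvS3", 1): {**NULLS},
            ("NaCl", "S3vS1", 1): {**NULLS},
            ("NaCl", "S2vS1", 1): {**NULLS},
        }
        for sid, v in strains.items():
            cols[("NaCl", "S4vS3", 1)][sid] = v["f4"]
            cols[("NaCl", "S4AvS3", 1)][sid] = v["f4a"]
            cols[("NaCl", "S3vS1", 1)][sid] = v["f3"]
            cols[("NaCl", "S2vS1", 1)][sid] = v["f2"]
        library_of = {f"n{i}": "homozygous" for i in range(len(NULLS))}
        library_of.update({
            "het_two_dose": "heterozygous", "het_one_dose": "heterozygous",
            "het_shared": "heterozygous", "damp_shared": "damp",
        })
        gene_of = {s: s.split("_", 1)[1] if "_" in s else s
                   for s in library_of}
        return make_cons(cols), library_of, gene_of

    def test_two_dose_rule(self):
        cons, libs, genes = self.single_rep_table()
        calls = sc.call_single_replicate(cons, "NaCl", "heterozygous",
                                         libs, genes)
        assert "het_two_dose" in calls.called
        assert calls.audit["het_two_dose"].added_by_two_dose_rule

    def test_single_dose_not_called(self):
        cons, libs, genes = self.single_rep_table()
        calls = sc.call_single_replicate(cons, "NaCl", "heterozygous",
                                         libs, genes)
        assert "het_one_dose" not in calls.called

    def test_multi_library_rescue(self):
        cons, libs, genes = self.single_rep_table()
        calls = sc.call_single_replicate(cons, "NaCl", "heterozygous",
                                         libs, genes)
        assert "het_shared" in calls.called
        assert calls.audit["het_shared"].route == "multi_library"

    def test_rejects_multi_replicate_library(self):
        cons, libs, genes = self.single_rep_table()
        # duplicate every column under a second replicate label
        dup = {}
        for (pre, comp, rep) in cons.columns:
            dup[(pre, comp, 1)] = cons[(pre, comp, rep)]
            dup[(pre, comp, 2)] = cons[(pre, comp, rep)]
        cons2 = make_cons({k: v.to_dict() for k, v in dup.items()})
        with pytest.raises(ConfigurationError, match="replicates"):
            sc.call_single_replicate(cons2, "NaCl", "heterozygous",
                                     libs, genes)


class TestCallLowdoseSensitive:
    def test_all_zero_empty(self):
        mat = pd.DataFrame(0.0, index=[f"s{i}" for i in range(10)],
                           columns=range(6))
        called, _ = sc.call_lowdose_sensitive(mat)
        assert called == set()

    def test_planted_hit_with_bh_oracle(self, rng):
        mat = pd.DataFrame(rng.normal(0, 0.1, size=(30, 6)),
                           index=[f"s{i}" for i in range(30)])
        mat.loc["s0"] = -3.0 + rng.normal(0, 0.05, size=6)
        called, result = sc.call_lowdose_sensitive(mat)
        assert "s0" in called
        # literal Benjamini-Hochberg ladder on the sorted p-values
        p = result["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        ladder = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ladder[::-1])[::-1]
        q_expected = np.empty(m)
        q_expected[order] = np.minimum(q_sorted, 1.0)
        assert result["q"].to_numpy() == pytest.approx(q_expected)

    def test_qmax_zero_empty(self, rng):
        mat = pd.DataFrame(rng.normal(-1, 0.1, size=(5, 6)))
        called, _ = sc.call_lowdose_sensitive(mat, q_max=0.0)
        assert called == set()

    def test_requires_three_replicates(self):
        mat = pd.DataFrame(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            sc.call_lowdose_sensitive(mat)

    def test_positive_mean_never_called(self, rng):
        mat = pd.DataFrame(rng.normal(2, 0.1, size=(5, 6)))
        called, _ = sc.call_lowdose_sensitive(mat)
        assert called == set()

    def test_constant_negative_rows_called(self):
        mat = pd.DataFrame(0.0, index=[f"s{i}" for i in range(20)],
                           columns=range(6))
        mat.loc["s3"] = -3.0
        called, _ = sc.call_lowdose_sensitive(mat)
        assert called == {"s3"}


class TestApplyExclusions:
    def test_equal_defect_removed(self):
        cons = basic_table(hit_f2=-2.0, hit_f4=-2.0)
        calls = sc.CallSet("NaCl", called={"hit"})
        out = sc.apply_exclusions(calls, set(), cons)
        assert out.called == set()
        assert out.audit["hit"].route == "excluded_equal_defect"

    def test_pretreatment_sensitive_removed(self):
        cons = basic_table(hit_f3=-3.0)
        calls = sc.CallSet("NaCl", called={"hit"})
        out = sc.apply_exclusions(calls, set(), cons)
        assert out.called == set()

    def test_disjoint_unchanged_and_idempotent(self):
        cons = basic_table()
        calls = sc.CallSet("NaCl", called={"hit"})
        once = sc.apply_exclusions(calls, {"n0"}, cons)
        assert once.called == {"hit"}
        twice = sc.apply_exclusions(once, {"n0"}, cons)
        assert twice.called == once.called

    def test_equal_tolerance(self):
        cons = basic_table(hit_f2=-1.9, hit_f4=-2.0)
        calls = sc.CallSet("NaCl", called={"hit"})
        assert sc.apply_exclusions(calls, set(), cons).called == {"hit"}
        assert sc.apply_exclusions(calls, set(), cons,
                                   equal_tol=0.2).called == set()


class TestMonotonicity:
    def make_exact_table(self, survival):
        cat = sp.make_catalog(25, seed=41)
        pl.plant_defects(cat, ["NaCl"], seed=42, n_acquired=4,
                         acquired_survival=0.6, n_pretreat_sensitive=2,
                         n_uniform_sensitive=2)
        target = cat[0]
        target.survival[pl.severe_label("NaCl", "1.0")] = survival
        states = pl.simulate_states(cat, ["NaCl"])["NaCl"]
        cols = {}
        for rep in (1, 2):  # noiseless replicates
            for name in ("S2vS1", "S3vS1", "S4vS3"):
                num, den = name.split("v")
                cols[("NaCl", name, rep)] = fit.compute_fitness(
                    states[num].as_series(), states[den].as_series()
                ).to_dict()
        return make_cons(cols), target.strain_id

    def test_stronger_defect_stays_called(self):
        for weak, strong in [(0.5, 0.3), (0.3, 0.1)]:
            cons_w, sid = self.make_exact_table(weak)
            cons_s, _ = self.make_exact_table(strong)
            called_w = sc.call_stringent(cons_w, "NaCl").called
            called_s = sc.call_stringent(cons_s, "NaCl").called
            if sid in called_w:
                assert sid in called_s


class TestReconcileGenes:
    def test_library_priority(self):
        calls = sc.CallSet("NaCl", called={"hom_g1", "damp_g1", "het_g1",
                                           "het_g2"})
        gene_of = {"hom_g1": "g1", "damp_g1": "g1", "het_g1": "g1",
                   "het_g2": "g2"}
        lib_of = {"hom_g1": "homozygous", "damp_g1": "damp",
                  "het_g1": "heterozygous", "het_g2": "heterozygous"}
        best = sc.reconcile_genes(calls, gene_of, lib_of)
        assert best == {"g1": "hom_g1", "g2": "het_g2"}
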