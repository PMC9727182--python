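import numpy as np
import pandas as pd
import pytest

from pkmarker.integration import auc_weights, integrate_cohort
from pkmarker.io import PKValidationError
from pkmarker.nca import compute_nca, nca_table
from pkmarker.published import (
    CVD_RELEVANT,
    DETECTION_PATTERN,
    EFFECT_VALIDATED,
)
from pkmarker.screening import (
    CriterionFlags,
    estimability_from_nca,
    favorable_pk,
    representativeness_test,
    screen_markers,
)
from pkmarker.simulate import (
    AnalyteDesign,
    DispositionModel,
    StudyDesign,
    simulate_cohort,
)

ALL = ("HSYA", "SYR", "p-CA", "SCU", "p-HBA", "RU")


def published_flags():
    favorable = favorable_pk(DETECTION_PATTERN)
    return [
        CriterionFlags(
            analyte=a,
            favorable_pk=a in favorable,
            representative=(a == "HSYA"),
            cvd_relevant=a in CVD_RELEVANT,
            effect_validated=a in EFFECT_VALIDATED,
        )
        for a in ALL
    ]


class TestFavorablePK:
    def test_published_detection_pattern(self):
        """Estimable-by-medium-dose rule reproduces the favorable set:
        all ingredients except rutin (estimable only at the high dose)."""
        assert favorable_pk(DETECTION_PATTERN) == {"HSYA", "SYR", "p-CA", "SCU", "p-HBA"}

    def test_all_estimable_at_low_all_favorable(self):
        assert favorable_pk({a: "low" for a in ALL}) == set(ALL)

    def test_table_input(self):
        tbl = pd.DataFrame(
            {"low": [True, False], "medium": [True, False], "high": [True, True]},
            index=["A", "B"],
        )
        assert favorable_pk(tbl) == {"A"}

    def test_empty_inputs_rejected(self):
        with pytest.raises(PKValidationError):
            favorable_pk({})
        with pytest.raises(PKValidationError):
            favorable_pk(pd.DataFrame())


class TestRepresentativeness:
    @staticmethod
    def tables(shift=0.0, n=6, seed=0):
        rng = np.random.default_rng(seed)
        base = {
            "t_half": 0.5, "c_max": 1000.0, "auc_0_t": 900.0, "auc_0_inf": 950.0,
            "vz": 0.1, "cl": 0.09, "mrt_0_t": 0.7, "mrt_0_inf": 0.8,
        }
        rows_c, rows_i = [], []
        for i in range(n):
            noise = rng.normal(1.0, 0.05, size=len(base))
            rows_c.append({k: v * w for (k, v), w in zip(base.items(), noise)})
            rows_i.append(
                {k: v * w * (1 + (shift if k.startswith("auc") else 0))
                 for (k, v), w in zip(base.items(), rng.normal(1.0, 0.05, len(base)))}
            )
        cand = pd.DataFrame(rows_c).assign(dose_group="high", analyte="A")
        integ = pd.DataFrame(rows_i).assign(dose_group="high", analyte="Z")
        return cand, integ

    def test_identical_samples_representative(self):
        cand, _ = self.tables()
        rep = representativeness_test(cand, cand.assign(analyte="Z"))
        assert rep.representative is True
        assert (rep.table.loc[rep.table["evaluable"], "p_value"] >= 0.4).all()

    def test_large_shift_not_representative(self):
        cand, integ = self.tables(shift=10 * 0.05)
        rep = representativeness_test(cand, integ)
        assert rep.representative is False
        sig = rep.table[rep.table["significant"]]
        assert set(sig["parameter"]) >= {"auc_0_t", "auc_0_inf"}

    def test_single_tail_halves_two_tailed_p(self):
        cand, integ = self.tables(shift=0.03, seed=4)
        p1 = representativeness_test(cand, integ, tail="single").table["p_value"]
        p2 = representativeness_test(cand, integ, tail="two").table["p_value"]
        np.testing.assert_allclose(p1, p2 / 2, rtol=1e-12)

    def test_sample_exchange_symmetry(self):
        cand, integ = self.tables(shift=0.04, seed=9)
        a = representativeness_test(cand, integ).table["p_value"]
        b = representativeness_test(
            integ.rename(columns={}), cand.assign(analyte="Z")
        ).table["p_value"]
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_missing_parameter_column_not_evaluable(self):
        cand, integ = self.tables()
        cand["t_half"] = np.nan
        rep = representativeness_test(cand, integ)
        cell = rep.table[(rep.table["parameter"] == "t_half")]
        assert not cell["evaluable"].iloc[0]

    def test_dominant_analyte_cohort(self):
        """In a cohort where one analyte carries ~99% of total exposure, the
        dominant analyte is representative of the AUC-weighted integrated
        profile and a ~1%-exposure analyte is not."""
        design = StudyDesign(
            analytes=(
                AnalyteDesign("DOM", DispositionModel(0.09, (0.06,)), 250.0, 0.3),
                AnalyteDesign("MINOR", DispositionModel(0.4, (0.3,)), 2.5, 0.3),
            ),
            dose_groups={"high": (4.0, 20)},
            residual_cv=0.15,
        )
        cohort = simulate_cohort(design, seed=17)
        doses = {"DOM": 250.0 * 4, "MINOR": 2.5 * 4}
        per = {a: [compute_nca(p, doses[a]) for p in cohort if p.analyte == a]
               for a in ("DOM", "MINOR")}
        mean_aucs = {a: float(np.mean([r.auc_0_t for r in per[a]])) for a in per}
        w = auc_weights(mean_aucs)
        assert w.omegas["DOM"] > 0.95
        integ_profiles = integrate_cohort(cohort, w)
        d_z = sum(w.omegas[a] * doses[a] for a in doses)
        integ_tbl = nca_table([compute_nca(p, d_z) for p in integ_profiles])
        dom_rep = representativeness_test(nca_table(per["DOM"]), integ_tbl)
        minor_rep = representativeness_test(nca_table(per["MINOR"]), integ_tbl)
        assert dom_rep.representative is True
        assert minor_rep.representative is False


class TestScreenMarkers:
    def test_published_criteria_single_marker(self):
        """The four published criterion sets intersect in exactly HSYA."""
        report = screen_markers(published_flags())
        assert report.markers == {"HSYA"}

    def test_singleton_all_true(self):
        flags = [
            CriterionFlags("A", True, True, True, True),
            CriterionFlags("B", True, False, True, True),
        ]
        assert screen_markers(flags).markers == {"A"}

    def test_empty_marker_set_valid(self):
        flags = [CriterionFlags("A", True, False, True, True)]
        assert screen_markers(flags).markers == set()

    def test_intersection_property(self):
        report = screen_markers(published_flags())
        for s in report.criterion_sets.values():
            assert report.markers <= s

    def test_monotonicity_adding_a_true_flag(self):
        flags = published_flags()
        report = screen_markers(flags)
        upgraded = [
            CriterionFlags(f.analyte, f.favorable_pk, f.representative,
                           True, f.effect_validated)
            for f in flags
        ]
        assert report.markers <= screen_markers(upgraded).markers

    def test_representative_requires_favorable(self):
        f = CriterionFlags("X", favorable_pk=False, representative=True,
                           cvd_relevant=True, effect_validated=True)
        assert f.representative is False

    def test_venn_regions_partition_analytes(self):
        report = screen_markers(published_flags())
        members = [a for s in report.venn_regions().values() for a in s]
        assert sorted(members) == sorted(ALL)


class TestEstimability:
    def test_counts_estimable_subjects(self):
        tbl = pd.DataFrame(
            {
                "analyte": ["A"] * 4 + ["B"] * 4,
                "dose_group": ["low", "low", "high", "high"] * 2,
                "t_half": [0.5, 0.6, 0.5, 0.6, np.nan, np.nan, 0.5, 0.4],
            }
        )
        est = estimability_from_nca(tbl, min_estimable=2)
        assert bool(est.loc["A", "low"]) and bool(est.loc["B", "high"])
        assert not bool(est.loc["B", "low"])
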