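"""Synthetic cohort generator: study accounting, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dsindex.cohort import apply_inclusion_filters, read_cohort, write_cohort
from dsindex.pathology import derive_outcomes, panel_variable_specs
from dsindex.synthetic import (SyntheticParams, TruncNormalVar, default_params,
                               generate_cohort, generate_pathology_panel,
                               inject_missing)
from dsindex.variables import default_variable_specs


class TestDefaultParams:
    def test_dementia_population_structure(self):
        p = default_params("dementia")
        assert p.n_cases + p.n_controls == 245
        assert p.n_cases == 97
        assert p.n_died_within_2y == 94

    def test_dementia_mmse_group_means(self):
        p = default_params("dementia")
        mmse = next(v for v in p.variables if v.name == "mmse_total")
        assert mmse.case[0] == 22.2
        assert mmse.control[0] == 25.3

    def test_pathology_population_size(self):
        p = default_params("pathology")
        assert p.n_included == 163
        assert p.n_cases == 59  # dementia at death

    def test_dementia_missing_counts(self):
        p = default_params("dementia")
        assert p.missing_counts == {"education_years": 3, "apoe_genotype": 3}

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            default_params("oncology")


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        p = default_params("dementia")
        a = generate_cohort(p, seed=5)
        b = generate_cohort(p, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_class_counts_exact(self):
        p = default_params("dementia")
        df = generate_cohort(p, seed=2)
        included, _ = apply_inclusion_filters(df, "dementia")
        y = included["outcome"]
        assert (int((y == 1).sum()), int((y == 0).sum())) == (97, 148)

    def test_prefilter_population_is_339(self):
        df = generate_cohort(default_params("dementia"), seed=0)
        assert len(df) == 339

    def test_passes_cohort_io_roundtrip_without_warnings(self, tmp_path):
        df = generate_cohort(default_params("dementia"), seed=1)
        path = str(tmp_path / "sim.csv")
        write_cohort(df, path)
        table = read_cohort(path, default_variable_specs("dementia"))
        assert table.warnings == 0
        assert len(table) == len(df)

    def test_continuous_means_converge_to_targets(self):
        # scale the included population x10 and check each continuous
        # variable's per-group mean against its target within 3 SE
        p = default_params("dementia")
        p = SyntheticParams(model_kind=p.model_kind, n_cases=970,
                            n_controls=1480, variables=p.variables,
                            follow_up=p.follow_up)
        df = generate_cohort(p, seed=7)
        for v in p.variables:
            if not (isinstance(v, TruncNormalVar) and v.kind == "continuous"):
                continue
            for label, (target, sd) in ((1, v.case), (0, v.control)):
                vals = df.loc[df["outcome"] == label, v.name]
                se = sd / np.sqrt(len(vals))
                assert abs(vals.mean() - target) < 3 * se, (v.name, label)

    def test_ordinal_variables_on_discrete_support(self):
        df = generate_cohort(default_params("dementia"), seed=3)
        assert (df["competence_daily"] % 1 == 0).all()
        assert df["competence_daily"].between(1, 6).all()
        assert df["mmse_total"].between(0, 30).all()

    def test_apoe_binaries_consistent_with_genotype(self):
        df = generate_cohort(default_params("dementia"), seed=4)
        ok = df["apoe_genotype"].notna()
        e2 = df.loc[ok, "apoe_genotype"].str.contains("e2").astype(float)
        assert (df.loc[ok, "apoe_e2_carrier"] == e2).all()
        assert df.loc[~ok, "apoe_e2_carrier"].isna().all()


class TestInjectMissing:
    def test_exact_counts(self):
        df = generate_cohort(default_params("dementia"), seed=1)
        assert int(df["education_years"].isna().sum()) == 3
        assert int(df["apoe_genotype"].isna().sum()) == 3

    def test_zero_counts_leave_table_unchanged(self):
        df = generate_cohort(default_params("dementia"), seed=1)
        out = inject_missing(df, {"bmi": 0}, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_same_seed_same_mask(self):
        df = generate_cohort(default_params("dementia"), seed=1)
        m1 = inject_missing(df, {"bmi": 10}, seed=3)["bmi"].isna()
        m2 = inject_missing(df, {"bmi": 10}, seed=3)["bmi"].isna()
        assert (m1 == m2).all()

    def test_count_exceeding_n_rejected(self):
        df = generate_cohort(default_params("dementia"), seed=1)
        with pytest.raises(ValueError):
            inject_missing(df, {"bmi": len(df) + 1}, seed=0)

    def test_outcome_never_masked(self):
        df = generate_cohort(default_params("dementia"), seed=1)
        with pytest.raises(ValueError):
            inject_missing(df, {"outcome": 1}, seed=0)


class TestGeneratePathologyPanel:
    def test_deterministic_and_sized(self):
        p = default_params("pathology")
        a = generate_pathology_panel(p, seed=11)
        b = generate_pathology_panel(p, seed=11)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 163
        assert int(a["outcome"].sum()) == 59

    def test_amyloid_present_count_near_target(self):
        # binomial(163, 0.77): +-4 sd band around 125.5
        counts = []
        for seed in range(5):
            df = generate_pathology_panel(default_params("pathology"), seed=seed)
            counts.append(derive_outcomes(df)["amyloid"].sum())
        sd = np.sqrt(163 * 0.77 * 0.23)
        assert abs(np.mean(counts) - 163 * 0.77) < 4 * sd / np.sqrt(5)

    def test_zero_prevalence_switches_outcome_off(self):
        p = default_params("pathology")
        p.pathology.prevalence["hs"] = 0.0
        df = generate_pathology_panel(p, seed=0)
        assert (df["hs_severity"] == "no_minor").all()

    def test_macroinfarct_counts_internally_consistent(self):
        df = generate_pathology_panel(default_params("pathology"), seed=2)
        assert (df["macroinfarct_count"] >=
                df["cortical_macroinfarct_count"] +
                df["wm_macroinfarct_count"]).all()

    def test_inconsistent_macroinfarct_targets_rejected(self):
        p = default_params("pathology")
        p.pathology.prevalence["macroinfarcts"] = 0.05  # below subtype floor
        with pytest.raises(ValueError, match="macroinfarct"):
            generate_pathology_panel(p, seed=0)

    def test_quantitative_magnitudes_zero_iff_absent(self):
        df = generate_pathology_panel(default_params("pathology"), seed=3)
        out = derive_outcomes(df)
        present = out["amyloid"] == 1.0
        assert (df.loc[present, "amyloid_load"] > 0).all()
        assert (df.loc[~present & out["amyloid"].notna(), "amyloid_load"] == 0).all()

    def test_roundtrip_with_panel_specs(self, tmp_path):
        df = generate_pathology_panel(default_params("pathology"), seed=4)
        path = str(tmp_path / "panel.csv")
        write_cohort(df, path)
        specs = default_variable_specs("pathology") + panel_variable_specs()
        table = read_cohort(path, specs)
        assert table.warnings == 0

    def test_neuropath_ad_prevalence_near_target(self):
        shares = []
        for seed in range(5):
            df = generate_pathology_panel(default_params("pathology"), seed=seed)
            shares.append(derive_outcomes(df)["neuropath_ad"].mean())
        assert abs(np.mean(shares) - 0.47) < 0.08
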