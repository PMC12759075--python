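import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from conftest import make_ion_frame
from lipdiff.differential import (
    DesignError,
    SampleInfo,
    StudyDesign,
    ThresholdConfig,
    bh_adjust,
    bh_adjust_grouped,
    impute_missing,
    merge_ions_to_cutsites,
    normalize_to_abundance,
    protein_abundance_lfq,
    run_differential,
    welch_test,
    welch_test_matrix,
)
from lipdiff.peptide_map import ProteinSeq, map_ions_to_sites
from lipdiff.structure_calls import call_proteome
from lipdiff.synthetic_data import SimConfig, simulate_dataset

T = ["t1", "t2", "t3"]
R = ["r1", "r2", "r3"]


def two_group_design():
    samples = [SampleInfo(s, "ko", "LiP", i + 1) for i, s in enumerate(T)]
    samples += [SampleInfo(s, "wt", "LiP", i + 1) for i, s in enumerate(R)]
    return StudyDesign(tuple(samples), ("ko", "wt"))


# ---------------------------------------------------------------------------
# imputation


class TestImputeMissing:
    cfg = ThresholdConfig()

    def test_condition_exclusive_ion_gets_floor(self):
        frame = make_ion_frame(
            [("P1", "PEP", 2, "m0", 1, 3, 1e6, 1.2e6, 0.9e6, None, None, None)],
            T + R,
        )
        out = impute_missing(frame, T, R, self.cfg, floor=1e3)
        assert out.loc[0, R].tolist() == [1e3, 1e3, 1e3]
        assert bool(out.loc[0, "imputed"])

    def test_complete_ion_unchanged(self):
        frame = make_ion_frame(
            [("P1", "PEP", 2, "m0", 1, 3, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)], T + R
        )
        out = impute_missing(frame, T, R, self.cfg, floor=1e3)
        assert out.loc[0, T + R].tolist() == [1, 2, 3, 4, 5, 6]
        assert not bool(out.loc[0, "imputed"])

    def test_under_observed_in_both_groups_dropped(self):
        frame = make_ion_frame(
            [("P1", "PEP", 2, "m0", 1, 3, 1.0, None, None, 4.0, None, None)],
            T + R,
        )
        out = impute_missing(frame, T, R, self.cfg, floor=1e3)
        assert out.empty

    def test_partial_observation_passes_through(self):
        frame = make_ion_frame(
            [("P1", "PEP", 2, "m0", 1, 3, 1.0, 2.0, None, 4.0, None, None)],
            T + R,
        )
        out = impute_missing(frame, T, R, self.cfg, floor=1e3)
        assert len(out) == 1
        assert np.isnan(out.loc[0, "r2"])  # one-of-three ref stays missing

    def test_nonpositive_floor_rejected(self):
        frame = make_ion_frame(
            [("P1", "PEP", 2, "m0", 1, 3, 1.0, 2.0, 3.0, None, None, None)],
            T + R,
        )
        with pytest.raises(ValueError):
            impute_missing(frame, T, R, self.cfg, floor=0.0)


# ---------------------------------------------------------------------------
# merging


def test_merge_sums_charge_states_of_same_site():
    protein = ProteinSeq("P1", "MKALRGDSKA")
    ions = make_ion_frame(
        [
            ("P1", "ALRGDS", 2, "m0", 3, 8, 5e5, 5e5, 5e5, 5e5, 5e5, 5e5),
            ("P1", "ALRGDS", 3, "m0", 3, 8, 1e5, 1e5, 1e5, 1e5, 1e5, 1e5),
        ],
        T + R,
    )
    annotated = map_ions_to_sites(ions, [protein])
    merged = merge_ions_to_cutsites(annotated, T + R)
    assert len(merged) == 1
    assert merged.loc[0, "n_ions"] == 2
    assert merged.loc[0, T].tolist() == [6e5] * 3


def test_merge_keeps_distinct_sites_separate():
    protein = ProteinSeq("P1", "MKALRGDSKA")
    ions = make_ion_frame(
        [
            ("P1", "ALRGDS", 2, "m0", 3, 8, 5e5, 5e5, 5e5, 5e5, 5e5, 5e5),
            ("P1", "ALRGD", 2, "m0", 3, 7, 1e5, 1e5, 1e5, 1e5, 1e5, 1e5),
        ],
        T + R,
    )
    merged = merge_ions_to_cutsites(map_ions_to_sites(ions, [protein]), T + R)
    assert len(merged) == 2
    assert set(merged["site_id"]) == {"PK@8", "PK@7"}
    assert (merged["n_ions"] == 1).all()


# ---------------------------------------------------------------------------
# Welch


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_hand_computed_example(self):
        t, df, p = welch_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0213116, abs=1e-6)

    def test_degenerate_constant_equal_groups(self):
        assert welch_test([0, 0, 0], [0, 0, 0])[2] == 1.0

    def test_too_few_replicates(self):
        with pytest.raises(DesignError):
            welch_test([1.0], [1, 2, 3])

    def test_matches_scipy_on_random_groups(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n1, n2 = rng.integers(2, 8, size=2)
            a, b = rng.normal(size=n1), rng.normal(size=n2) + rng.normal()
            t, df, p = welch_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_matrix_handles_nan_as_missing(self):
        a = np.array([[1.0, 2.0, 3.0, np.nan]])
        b = np.array([[4.0, 5.0, 6.0, np.nan]])
        t, df, p = welch_test_matrix(a, b)
        ref = stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False)
        assert t[0] == pytest.approx(ref.statistic, rel=1e-12)


# ---------------------------------------------------------------------------
# BH


class TestBH:
    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_and_boundary(self):
        assert bh_adjust([0.5]).tolist() == [0.5]
        assert bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_dominates_raw_p_and_matches_statsmodels(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1)
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert adj == pytest.approx(ref, rel=1e-12, abs=1e-15)

    def test_order_preserving_on_sorted_input(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(40))
        adj = bh_adjust(p)
        assert np.all(np.diff(adj) >= -1e-15)

    def test_grouped_adjustment_is_per_family(self):
        p = pd.Series([0.01, 0.02, 0.03, 0.04])
        groups = pd.Series(["a", "a", "b", "b"])
        out = bh_adjust_grouped(p, groups)
        assert out.tolist() == pytest.approx([0.02, 0.02, 0.04, 0.04])


# ---------------------------------------------------------------------------
# abundance + normalization


def test_normalize_subtracts_protein_log2fc():
    sites = pd.DataFrame(
        {"protein_id": ["P1", "P2", "P3"], "log2fc_raw": [2.0, 1.5, -1.0]}
    )
    abundance = pd.DataFrame(
        {"protein_id": ["P1", "P2", "P3"], "log2fc": [2.0, 0.0, 1.0]}
    )
    out = normalize_to_abundance(sites, abundance)
    assert out["log2fc_norm"].tolist() == pytest.approx([0.0, 1.5, -2.0])
    assert out["normalized"].all()


def test_normalize_flags_proteins_without_abundance():
    sites = pd.DataFrame({"protein_id": ["P9"], "log2fc_raw": [1.2]})
    abundance = pd.DataFrame({"protein_id": ["P1"], "log2fc": [1.0]})
    out = normalize_to_abundance(sites, abundance)
    assert out.loc[0, "log2fc_norm"] == 1.2
    assert not out.loc[0, "normalized"]


def test_protein_abundance_doubled_intensities_give_log2fc_one():
    protein = ProteinSeq("P1", "MKALRGDSKA")
    # fully tryptic peptide, doubled in the test condition, noise-free
    ions = make_ion_frame(
        [("P1", "ALR", 2, "m0", 3, 5, 2e6, 2e6, 2e6, 1e6, 1e6, 1e6)], T + R
    )
    design = StudyDesign(
        tuple(
            [SampleInfo(s, "ko", "trypsin_only", i + 1) for i, s in enumerate(T)]
            + [SampleInfo(s, "wt", "trypsin_only", i + 1) for i, s in enumerate(R)]
        ),
        ("ko", "wt"),
    )
    out = protein_abundance_lfq(ions, design, [protein], ThresholdConfig())
    assert len(out) == 1
    assert out.loc[0, "log2fc"] == pytest.approx(1.0)


def test_protein_abundance_skips_half_tryptic_only_proteins():
    protein = ProteinSeq("P1", "MKALRGDSKA")
    ions = make_ion_frame(  # half-tryptic: not usable for abundance
        [("P1", "ALRG", 2, "m0", 3, 6, 1e6, 1e6, 1e6, 1e6, 1e6, 1e6)], T + R
    )
    design = StudyDesign(
        tuple(
            [SampleInfo(s, "ko", "trypsin_only", i + 1) for i, s in enumerate(T)]
            + [SampleInfo(s, "wt", "trypsin_only", i + 1) for i, s in enumerate(R)]
        ),
        ("ko", "wt"),
    )
    out = protein_abundance_lfq(ions, design, [protein], ThresholdConfig())
    assert out.empty


# ---------------------------------------------------------------------------
# full pipeline properties


def test_run_differential_empty_input_gives_empty_result():
    design = two_group_design()
    empty = pd.DataFrame(columns=["protein_id", "peptide", "charge", "mod_key",
                                  "start", "end", *T, *R])
    res = run_differential(empty, empty, design, [], ThresholdConfig())
    assert res.cutsites.empty


def test_run_differential_requires_two_replicates():
    samples = (
        SampleInfo("t1", "ko", "LiP", 1),
        SampleInfo("r1", "wt", "LiP", 1),
        SampleInfo("r2", "wt", "LiP", 2),
    )
    design = StudyDesign(samples, ("ko", "wt"))
    with pytest.raises(DesignError):
        run_differential(pd.DataFrame({"t1": [1.0]}), pd.DataFrame(), design, [],
                         ThresholdConfig())


def test_single_true_effect_detected_and_decoys_clean():
    cfg = SimConfig(n_proteins=12, frac_perturbed_proteins=1 / 12,
                    sites_per_perturbed_protein=(1, 1), exclusive_site_prob=0.0,
                    frac_abundance_shifted=0.0, site_effect_fold=4.0,
                    cv=0.2, detection_prob=1.0, seed=5)
    ds = simulate_dataset(cfg)
    res = run_differential(ds.lip_ions, ds.control_ions, ds.design,
                           ds.proteome, ThresholdConfig())
    (pid,) = ds.truth.perturbed_proteins
    (site,) = ds.truth.perturbed_sites[pid]
    hit = res.cutsites[(res.cutsites.protein_id == pid)
                       & (res.cutsites.site_id == f"PK@{site['position']}")]
    assert len(hit) == 1 and bool(hit["significant"].iloc[0])
    decoy_sig = res.cutsites[(res.cutsites.protein_id != pid)
                             & res.cutsites.significant]
    assert len(decoy_sig) == 0


def test_label_swap_negates_normalized_fold_changes(small_dataset):
    ds = small_dataset
    cfg = ThresholdConfig()
    fwd = run_differential(ds.lip_ions, ds.control_ions, ds.design,
                           ds.proteome, cfg)
    rev = run_differential(ds.lip_ions, ds.control_ions, ds.design.swapped(),
                           ds.proteome, cfg)
    key = ["protein_id", "site_id"]
    merged = fwd.cutsites.merge(rev.cutsites, on=key, suffixes=("_f", "_r"))
    assert len(merged) == len(fwd.cutsites) == len(rev.cutsites)
    assert np.allclose(merged["log2fc_norm_f"], -merged["log2fc_norm_r"],
                       atol=1e-9)
    assert np.allclose(merged["p_raw_f"], merged["p_raw_r"], atol=1e-12)


def test_uniform_abundance_scaling_yields_no_significant_sites():
    # multiply every intensity of the test condition by a constant,
    # noise-free: normalization must cancel the confound exactly
    cfg = SimConfig(n_proteins=8, frac_perturbed_proteins=0.0,
                    frac_abundance_shifted=1.0, abundance_fold_range=(6.0, 6.0),
                    cv=0.0, detection_prob=1.0, seed=9)
    ds = simulate_dataset(cfg)
    res = run_differential(ds.lip_ions, ds.control_ions, ds.design,
                           ds.proteome, ThresholdConfig())
    assert np.abs(res.cutsites["log2fc_norm"]).max() < 1e-9
    assert not res.cutsites["significant"].any()


def test_sensitivity_monotone_in_effect_size_and_replicates():
    sens = {}
    for fold, reps in [(2.0, 3), (4.0, 3), (8.0, 3), (4.0, 5)]:
        cfg = SimConfig(n_proteins=80, frac_perturbed_proteins=0.15,
                        site_effect_fold=fold, replicates=reps, seed=21)
        ds = simulate_dataset(cfg)
        res = run_differential(ds.lip_ions, ds.control_ions, ds.design,
                               ds.proteome, ThresholdConfig())
        calls, _ = call_proteome(res.cutsites)
        truth = set(ds.truth.perturbed_proteins)
        called = set(calls[calls.status == "perturbed"].protein_id)
        sens[(fold, reps)] = len(called & truth) / len(truth)
    assert sens[(2.0, 3)] <= sens[(4.0, 3)] <= sens[(8.0, 3)]
    assert sens[(4.0, 3)] <= sens[(4.0, 5)]
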