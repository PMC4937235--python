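"""Multi-tissue screening, signature classification and set algebra."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from hccsig import (
    CohortConfig,
    SignatureScreen,
    SignatureSet,
    SignatureThresholds,
    build_tissue_profile,
    classify_liver_specific,
    classify_tumor_associated,
    classify_tumor_specific,
    collapse_to_genes,
    signature_overlap,
    simulate_expression,
)
from hccsig import reference_sets
from hccsig.signature import venn_partition

from conftest import planted


def toy_cohort(tumor_values, liver_value=0.0, tissue_values=None, n_tumor=10):
    """One-probe cohort with explicit per-sample tumor values."""
    tissue_values = tissue_values if tissue_values is not None else [0.0, 0.0]
    rows = []
    cols = {}
    for i, v in enumerate(tumor_values):
        cols[f"t{i}"] = v
        rows.append((f"t{i}", "tumor", "HCV", ""))
    for i in range(2):
        cols[f"l{i}"] = liver_value
        rows.append((f"l{i}", "normal_liver", "NA", ""))
    for ti, tv in enumerate(tissue_values):
        for r in range(2):
            cols[f"n{ti}_{r}"] = tv
            rows.append((f"n{ti}_{r}", "normal_tissue", "NA", f"tt{ti}"))
    sheet = pd.DataFrame(rows, columns=["sample_id", "group", "etiology", "tissue_type"])
    sheet = sheet.set_index("sample_id")
    matrix = pd.DataFrame([cols], index=["probe1"])[sheet.index.tolist()]
    probe_map = pd.Series({"probe1": "GENE1"})
    return matrix, sheet, probe_map


class TestTissueProfile:
    def test_constant_matrix_gives_zero_fold_changes(self):
        matrix, sheet, _ = toy_cohort([7.0] * 5, liver_value=7.0, tissue_values=[7.0, 7.0])
        profile = build_tissue_profile(matrix, sheet)
        assert (profile.tumor_log2fc.to_numpy() == 0).all()
        assert (profile.tissue_log2fc.to_numpy() == 0).all()
        assert (profile.liver_log2fc == 0).all()

    def test_zero_noise_tumor_specific_matches_direct_recomputation(self):
        config = CohortConfig(noise_sd=0.0, seed=2, n_genes=100,
                              n_planted_per_class={"tumor_specific": 5,
                                                   "tumor_associated": 5,
                                                   "liver_specific": 5,
                                                   "down_in_tumor": 5})
        expr, sheet, probe_map, truth = simulate_expression(config)
        profile = build_tissue_profile(expr, sheet)
        non_tumor = sheet.index[sheet["group"] != "tumor"]
        for gene in planted(truth, "tumor_specific"):
            for probe in probe_map.index[probe_map == gene]:
                ref = expr.loc[probe, non_tumor].mean()  # direct oracle
                expected = expr.loc[probe, sheet.index[sheet["group"] == "tumor"]] - ref
                np.testing.assert_allclose(
                    profile.tumor_log2fc.loc[probe], expected.to_numpy(), atol=1e-12
                )

    def test_zero_noise_liver_gene_liver_fc_is_brute_force_difference(self):
        config = CohortConfig(noise_sd=0.0, seed=2, n_genes=100,
                              n_planted_per_class={"liver_specific": 5})
        expr, sheet, probe_map, truth = simulate_expression(config)
        profile = build_tissue_profile(expr, sheet)
        liver = sheet.index[sheet["group"] == "normal_liver"]
        tissue = sheet.index[sheet["group"] == "normal_tissue"]
        for gene in planted(truth, "liver_specific"):
            for probe in probe_map.index[probe_map == gene]:
                brute = expr.loc[probe, liver].mean() - expr.loc[probe, tissue].mean()
                assert profile.liver_log2fc.loc[probe] == pytest.approx(brute, abs=1e-12)
                assert profile.liver_log2fc.loc[probe] > 0

    def test_requires_two_tissue_types(self):
        matrix, sheet, _ = toy_cohort([1.0] * 3, tissue_values=[0.0])
        with pytest.raises(ValueError, match="tissue types"):
            build_tissue_profile(matrix, sheet)


@pytest.fixture(scope="module")
def fitted(default_cohort):
    _, expr, sheet, probe_map, truth = default_cohort
    screen = SignatureScreen(expr, sheet, probe_map, normalized=True)
    return screen.fit(), truth


class TestClassification:
    def test_liver_specific_genes_all_recovered(self, fitted):
        res, truth = fitted
        assert planted(truth, "liver_specific") <= res.signature_set.liver_specific

    def test_tumor_specific_genes_never_liver_specific(self, fitted):
        res, truth = fitted
        assert not (planted(truth, "tumor_specific") & res.signature_set.liver_specific)

    def test_tumor_associated_includes_both_up_classes(self, fitted):
        res, truth = fitted
        assoc = res.signature_set.tumor_associated
        assert planted(truth, "tumor_associated") <= assoc
        assert planted(truth, "tumor_specific") <= assoc

    def test_liver_specific_genes_excluded_from_tumor_associated(self, fitted):
        res, truth = fitted
        assert not (planted(truth, "liver_specific") & res.signature_set.tumor_associated)

    def test_tumor_specific_classification_is_exact(self, fitted):
        res, truth = fitted
        assert res.signature_set.tumor_specific == planted(truth, "tumor_specific")

    def test_partially_elevated_genes_rejected_by_tissue_gate(self, fitted):
        res, truth = fitted
        assert not (planted(truth, "tumor_associated") & res.signature_set.tumor_specific)

    def test_subset_invariant(self, fitted):
        res, _ = fitted
        assert res.signature_set.tumor_specific <= res.signature_set.tumor_associated

    def test_exactly_eighty_percent_tumor_fraction_rejected(self):
        # 8/10 tumor samples elevated: fraction == 0.80, strict > rejects
        matrix, sheet, probe_map = toy_cohort([10.0] * 8 + [0.0] * 2)
        profile = build_tissue_profile(matrix, sheet)
        got = classify_tumor_specific(profile, {"GENE1"}, probe_map)
        assert got == set()
        # 9/10 passes
        matrix, sheet, probe_map = toy_cohort([10.0] * 9 + [0.0])
        profile = build_tissue_profile(matrix, sheet)
        assert classify_tumor_specific(profile, {"GENE1"}, probe_map) == {"GENE1"}

    def test_constant_gene_not_liver_specific(self):
        matrix, sheet, probe_map = toy_cohort([7.0] * 5, liver_value=7.0,
                                              tissue_values=[7.0, 7.0])
        profile = build_tissue_profile(matrix, sheet)
        assert classify_liver_specific(profile, probe_map) == set()

    def test_empty_up_probes_gives_empty_tumor_associated(self, default_cohort):
        _, expr, sheet, probe_map, _ = default_cohort
        profile = build_tissue_profile(expr, sheet)
        assert classify_tumor_associated(profile, set(), probe_map) == set()

    def test_sensitivity_non_increasing_in_noise(self):
        # seed-averaged sweep: recovery can only degrade as noise grows
        noise_levels = (0.3, 1.0, 1.8)
        mean_sens = []
        for noise in noise_levels:
            sens = []
            for seed in (1, 2, 3):
                config = CohortConfig(noise_sd=noise, seed=seed, n_genes=400)
                expr, sheet, probe_map, truth = simulate_expression(config)
                res = SignatureScreen(expr, sheet, probe_map, normalized=True).fit()
                want = planted(truth, "tumor_specific")
                sens.append(len(res.signature_set.tumor_specific & want) / len(want))
            mean_sens.append(np.mean(sens))
        assert mean_sens[0] == 1.0
        assert all(a >= b for a, b in zip(mean_sens, mean_sens[1:]))


class TestCollapse:
    def test_any_and_all_modes(self):
        pm = pd.Series({"p1": "GENE1", "p2": "GENE1", "p3": "GENE2"})
        assert collapse_to_genes({"p1"}, pm, "any") == {"GENE1"}
        assert collapse_to_genes({"p1"}, pm, "all") == set()
        assert collapse_to_genes({"p1", "p2"}, pm, "all") == {"GENE1"}

    def test_unmapped_probes_listed(self):
        pm = pd.Series({"p1": "GENE1"})
        with pytest.raises(KeyError, match="pX"):
            collapse_to_genes({"p1", "pX"}, pm)

    def test_pigeonhole_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n_genes = rng.integers(2, 20)
            genes = [f"G{i}" for i in range(n_genes)]
            pm = pd.Series({
                f"pr{j}": genes[rng.integers(n_genes)] for j in range(rng.integers(2, 60))
            })
            probes = set(rng.choice(pm.index, size=rng.integers(1, len(pm) + 1),
                                    replace=False))
            assert len(collapse_to_genes(probes, pm)) <= len(probes)


class TestOverlap:
    def test_venn_cells_match_bitmask_oracle(self):
        rng = np.random.default_rng(13)
        universe = [f"G{i}" for i in range(40)]
        sets = {name: set(rng.choice(universe, size=rng.integers(0, 30), replace=False))
                for name in ("A", "B", "C")}
        cells = venn_partition(sets)
        # brute-force membership bitmask enumeration
        for mask in product([False, True], repeat=3):
            if not any(mask):
                continue
            expected = sorted(
                g for g in universe
                if tuple(g in sets[n] for n in ("A", "B", "C")) == mask
            )
            assert cells[mask] == expected
        total = sum(len(v) for v in cells.values())
        assert total == len(set().union(*sets.values()))

    def test_identical_sets_intersect_fully(self):
        s = SignatureSet("X", frozenset(), frozenset({"A", "B"}), frozenset({"A", "B"}))
        t = SignatureSet("Y", frozenset(), frozenset({"A", "B"}), frozenset({"A", "B"}))
        table = signature_overlap([s, t], "tumor_specific")
        both = table[(table["X"]) & (table["Y"])]
        assert both["n"].iloc[0] == 2
        assert (table[~(table["X"] & table["Y"])]["n"] == 0).all()

    def test_published_signatures_three_way_intersection(self):
        # the printed etiology-stratified lists share exactly three genes
        inter = (set(reference_sets.HBV_HCC_SPECIFIC)
                 & set(reference_sets.HCV_HCC_SPECIFIC)
                 & set(reference_sets.HCC_SPECIFIC))
        assert inter == {"CDKN2A", "IGF2BP3", "ZNF623"}
        assert reference_sets.common_to_all_settings() == inter


class TestSignatureSetInvariants:
    def test_tumor_specific_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            SignatureSet("X", frozenset(), frozenset({"A"}), frozenset({"B"}))

    def test_liver_and_tumor_associated_disjoint(self):
        with pytest.raises(ValueError, match="overlap"):
            SignatureSet("X", frozenset({"A"}), frozenset({"A"}), frozenset())

    def test_gene_planted_in_all_tumors_appears_in_every_setting(self, default_cohort):
        _, expr, sheet, probe_map, truth = default_cohort
        screen = SignatureScreen(expr, sheet, probe_map, normalized=True)
        strat = screen.fit_stratified()
        want = planted(truth, "tumor_specific")
        for name, res in strat.results.items():
            assert want <= res.signature_set.tumor_specific, name
        assert strat.common_genes("tumor_specific") == want
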