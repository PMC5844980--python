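"""Lineage filters, replicate selection, rank collapsing, TMM, Venn."""

import numpy as np
import pandas as pd
import pytest

import ampliem as am
from ampliem.tables import OtuTable

# edgeR::calcNormFactors(method="TMM") on the seeded fixture below
_EDGER_FACTORS = [1.02708428, 0.96198096, 1.01988814, 0.97329457, 1.00832581, 1.01118289]


def tax_frame(rows):
    return pd.DataFrame(
        rows, columns=list(am.RANKS)
    )


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        {
            "s1": [5, 3, 2, 1, 4, 6, 2, 1, 3, 2],
            "s2": [4, 2, 1, 2, 5, 7, 1, 2, 2, 1],
        },
        index=[f"o{i}" for i in range(10)],
    )
    lineages = [
        ["Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Rg1"],
        ["Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Rg1"],
        ["Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bg1"],
        ["Archaea", "Euryarchaeota", None, None, None, None],
        ["Bacteria", "Cyanobacteria", None, None, None, None],
        ["Bacteria", "Proteobacteria", "Alpha", "Rickettsiales", "mitochondria", None],
        ["Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Pg1"],
        ["Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", None],
        ["Bacteria", "Firmicutes", None, None, None, None],
        [None, None, None, None, None, None],  # unassigned
    ]
    tax = pd.DataFrame(lineages, index=counts.index, columns=list(am.RANKS))
    return OtuTable(counts=counts, taxonomy=tax)


class TestFilterTaxa:
    def test_rules_remove_expected_otus(self, tiny_table):
        out, removed = am.filter_taxa(tiny_table, exclude_ids=("o6",))
        assert removed == {"organelle": 1, "domain": 1, "phylum": 1, "excluded": 1}
        assert set(out.counts.index) == {"o0", "o1", "o2", "o7", "o8", "o9"}

    def test_archaea_removed(self, tiny_table):
        out, _ = am.filter_taxa(tiny_table)
        assert "o3" not in out.counts.index

    def test_identity_on_clean_table(self, tiny_table):
        clean = tiny_table.subset_otus(["o0", "o1", "o2"])
        out, removed = am.filter_taxa(clean)
        assert list(out.counts.index) == ["o0", "o1", "o2"]
        assert sum(removed.values()) == 0

    def test_idempotent(self, tiny_table):
        once, _ = am.filter_taxa(tiny_table)
        twice, removed = am.filter_taxa(once)
        assert list(once.counts.index) == list(twice.counts.index)
        assert sum(removed.values()) == 0


class TestSelectReplicates:
    def test_identical_profiles_consistent_larger_kept(self):
        counts = pd.DataFrame(
            {
                "a_1": [10, 5, 0], "a_2": [20, 10, 0],
                "b_1": [0, 2, 20], "b_2": [0, 1, 12],
            },
            index=["o1", "o2", "o3"],
        )
        t = OtuTable(counts)
        out, report = am.select_replicates(
            t, {"a": ("a_1", "a_2"), "b": ("b_1", "b_2")}
        )
        assert report["consistent"].all()
        assert report.loc["a", "kept"] == "a_2"
        assert set(out.counts.columns) == {"a", "b"}

    def test_swapped_profile_flagged(self):
        counts = pd.DataFrame(
            {
                "a_1": [10, 0, 0], "a_2": [0, 0, 10],  # a_2 looks like b
                "b_1": [0, 0, 11], "b_2": [0, 0, 12],
            },
            index=["o1", "o2", "o3"],
        )
        t = OtuTable(counts)
        _, report = am.select_replicates(t, {"a": ("a_1", "a_2"), "b": ("b_1", "b_2")})
        assert not report.loc["a", "consistent"]

    def test_missing_mate_fails(self):
        t = OtuTable(pd.DataFrame({"a_1": [1]}, index=["o1"]))
        with pytest.raises(ValueError):
            am.select_replicates(t, {"a": ("a_1", "a_2")})

    def test_simulated_replicates_all_covered(self, small_config, small_study):
        counts = am.simulate_counts(
            small_study.references, small_study.truth, small_config,
            per_replicate=True,
        )
        t = OtuTable(counts)
        pairs = {s: (f"{s}_1", f"{s}_2") for s in small_study.metadata.index}
        out, report = am.select_replicates(t, pairs)
        assert len(report) == len(pairs)
        assert out.counts.shape[1] == len(pairs)


class TestCollapseRank:
    def test_same_genus_summed(self, tiny_table):
        out = am.collapse_rank(tiny_table.subset_otus(["o0", "o1"]), "genus")
        assert out.counts.loc["Rg1"].tolist() == [8, 6]

    def test_family_truncated_label(self, tiny_table):
        out = am.collapse_rank(tiny_table.subset_otus(["o7"]), "genus")
        assert list(out.counts.index) == ["Lachnospiraceae (family)"]

    def test_phylum_collapse_conserves_library(self, tiny_table):
        out = am.collapse_rank(tiny_table, "phylum")
        assert (out.counts.sum(axis=0) == tiny_table.counts.sum(axis=0)).all()


class TestRelativeAbundance:
    def test_columns_sum_to_one(self, tiny_table):
        rel = am.relative_abundance(tiny_table)
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_singleton_in_large_library(self):
        counts = pd.DataFrame({"s": [1, 9999]}, index=["a", "b"])
        rel = am.relative_abundance(OtuTable(counts))
        assert rel.loc["a", "s"] == pytest.approx(1e-4)

    def test_zero_library_dropped_with_warning(self):
        counts = pd.DataFrame({"s": [1], "t": [0]}, index=["a"])
        with pytest.warns(UserWarning):
            rel = am.relative_abundance(OtuTable(counts))
        assert list(rel.columns) == ["s"]


class TestTmm:
    def test_identical_libraries_unit_factors(self):
        counts = pd.DataFrame(
            np.tile([[5], [10], [3], [8]], (1, 3)),
            index=list("abcd"), columns=["s1", "s2", "s3"],
        )
        f = am.tmm_factors(counts)
        assert np.allclose(f.composition_factor, 1.0)
        assert np.allclose(f.scaling_factor, 1.0)

    def test_tripled_library_scaling_ratio_three(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(30, size=40) + 1
        counts = pd.DataFrame({"s1": base, "s2": base * 3})
        f = am.tmm_factors(counts)
        assert np.allclose(f.composition_factor, 1.0, atol=1e-9)
        assert f.scaling_factor["s2"] / f.scaling_factor["s1"] == pytest.approx(3.0)

    def test_matches_edger_on_fixture(self):
        rng = np.random.default_rng(21)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.02, size=(80, 6)),
            index=[f"t{i}" for i in range(80)],
            columns=[f"s{j}" for j in range(6)],
        )
        counts.iloc[:, 3] *= 3
        f = am.tmm_factors(counts)
        assert np.allclose(f.composition_factor.to_numpy(), _EDGER_FACTORS, atol=1e-6)

    def test_two_fold_depth_recovered(self):
        rng = np.random.default_rng(8)
        props = rng.dirichlet(np.full(200, 2.0))
        s1 = rng.multinomial(20000, props)
        s2 = rng.multinomial(40000, props)
        f = am.tmm_factors(pd.DataFrame({"s1": s1, "s2": s2})).scaling_factor
        assert abs(np.log2(f["s2"] / f["s1"]) - 1.0) < 0.05

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(20, size=(50, 5)) + 1)
        f = am.tmm_factors(counts)
        assert np.exp(np.mean(np.log(f.composition_factor))) == pytest.approx(1.0, abs=1e-9)
        assert np.exp(np.mean(np.log(f.scaling_factor))) == pytest.approx(1.0, abs=1e-9)


class TestCoreSharedUnique:
    def test_identical_groups_all_shared(self):
        counts = pd.DataFrame(
            np.tile([[3], [2], [1]], (1, 6)),
            index=["o1", "o2", "o3"],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["O", "O", "V", "V", "VG", "VG"], index=counts.columns)
        res = am.core_shared_unique(OtuTable(counts), groups)
        assert res["venn"]["111"] == 3
        assert sum(v for k, v in res["venn"].items() if k != "111") == 0
        assert res["core_shared"]

    def test_group_unique_core_otu(self):
        counts = pd.DataFrame(0, index=["core", "o_only"], columns=[f"s{i}" for i in range(9)])
        counts.loc["core"] = 5
        counts.loc["o_only", ["s0", "s1", "s2"]] = [4, 4, 4]  # all O samples
        groups = pd.Series(["O"] * 3 + ["V"] * 3 + ["VG"] * 3, index=counts.columns)
        res = am.core_shared_unique(OtuTable(counts), groups)
        assert "o_only" in res["core"]["O"]
        assert res["venn"]["100"] == 1
        assert not res["core_shared"]  # the O core is not shared

    def test_simulated_core_property(self):
        # the power-law prevalence core emerges with cohort-scale groups
        cfg = am.SimulationConfig(
            seed=5, n_otus=60, group_sizes={"O": 12, "V": 12, "VG": 12},
            library_mean=3000, library_range=(1500, 6000),
            richness_mean={"O": 30, "V": 36, "VG": 33}, richness_sd=4,
        )
        study = am.simulate_study(cfg)
        counts = am.simulate_counts(study.references, study.truth, cfg)
        res = am.core_shared_unique(
            OtuTable(counts), study.metadata["group"], prevalence=0.90
        )
        assert res["core_shared"]
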