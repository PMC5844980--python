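"""Generator ground truth: separation, error rates, determinism, cohort."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ampliem as am
from ampliem.simulate import _find_runs


class TestReferences:
    def test_single_reference(self):
        cfg = am.SimulationConfig(seed=1, n_otus=1)
        refs = am.generate_references(cfg)
        assert len(refs) == 1
        assert set(refs[0].sequence) <= set("ACGT")
        assert refs[0].lineage[0] == "Bacteria"

    def test_well_separated_references_verified_by_aligner(self):
        cfg = am.SimulationConfig(seed=7, n_otus=10, near_pair_fraction=0.0)
        refs = am.generate_references(cfg)
        d = am.distance_matrix({r.id: r.sequence for r in refs})
        off = d.to_numpy()[~np.eye(10, dtype=bool)]
        assert off.min() >= cfg.min_separation

    def test_near_pairs_fall_in_stress_band(self):
        cfg = am.SimulationConfig(seed=7, n_otus=10, near_pair_fraction=0.2)
        refs = am.generate_references(cfg)
        d = am.distance_matrix({r.id: r.sequence for r in refs})
        off = d.to_numpy()[~np.eye(10, dtype=bool)]
        assert 0.02 <= off.min() <= 0.07  # mutated copies land near 3.5-5.5%

    def test_truncated_lineage_count_is_exact(self):
        cfg = am.SimulationConfig(seed=5, n_otus=10, fraction_truncated_lineage=0.2)
        refs = am.generate_references(cfg)
        assert sum(1 for r in refs if len(r.lineage) == 5) == 2

    def test_impossible_separation_fails(self):
        with pytest.raises(ValueError):
            am.generate_references(am.SimulationConfig(min_separation=0.5))

    def test_sequence_lengths_in_range(self):
        cfg = am.SimulationConfig(seed=2, n_otus=15)
        for r in am.generate_references(cfg):
            assert 400 <= len(r.sequence) <= 470


class TestReads:
    def test_error_free_reads_are_exact_copies(self):
        cfg = am.SimulationConfig(
            seed=4, n_otus=5, substitution_rate=0.0, homopolymer_indel_rate=0.0,
            group_sizes={"O": 2}, replicates=1, library_mean=50,
            library_range=(20, 100), richness_mean={"O": 5}, richness_sd=0,
        )
        study = am.simulate_study(cfg)
        reads = am.simulate_reads(study.references, study.truth, cfg)
        seq_of = {r.id: r.sequence for r in study.references}
        for sample, rs in reads.items():
            for r in rs:
                assert r.bases == seq_of[study.truth.read_sources[r.id]]

    def test_substitution_rate_recovered(self):
        rate = 0.005
        cfg = am.SimulationConfig(
            seed=9, n_otus=3, substitution_rate=rate, homopolymer_indel_rate=0.0,
            group_sizes={"O": 1}, replicates=1, library_mean=1000,
            library_range=(1000, 1000), richness_mean={"O": 3}, richness_sd=0,
        )
        study = am.simulate_study(cfg)
        reads = am.simulate_reads(study.references, study.truth, cfg)
        seq_of = {r.id: r.sequence for r in study.references}
        mism = total = 0
        for rs in reads.values():
            for r in rs:
                ref = seq_of[study.truth.read_sources[r.id]]
                mism += sum(1 for x, y in zip(r.bases, ref) if x != y)
                total += len(ref)
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(mism / total - rate) < 3 * se

    def test_homopolymer_indels_only_change_run_lengths(self):
        # with substitutions off, an error-bearing read must have the same
        # run-length-encoded base sequence as its source, with run lengths
        # changed by at most one and only at runs of length >= 2
        from ampliem.simulate import _sequencing_errors

        def rle(s):
            out = []
            for c in s:
                if out and out[-1][0] == c:
                    out[-1][1] += 1
                else:
                    out.append([c, 1])
            return out

        cfg = am.SimulationConfig(substitution_rate=0.0, homopolymer_indel_rate=0.5)
        rng_seq = np.random.default_rng(13)
        rng_err = np.random.default_rng(14)
        changed = 0
        for _ in range(20):
            ref = "".join(rng_seq.choice(list("ACGT"), 200))
            read = _sequencing_errors(rng_err, ref, cfg)
            r_ref, r_read = rle(ref), rle(read)
            assert [b for b, _ in r_ref] == [b for b, _ in r_read]
            for (b, n_ref), (_, n_read) in zip(r_ref, r_read):
                assert abs(n_ref - n_read) <= 1
                if n_ref != n_read:
                    assert n_ref >= 2  # edits only inside true runs
                    changed += 1
        assert changed > 0

    def test_find_runs(self):
        assert _find_runs("AACCCGT") == [(0, 2), (2, 3)]
        assert _find_runs("ACGT") == []

    def test_determinism_same_seed_identical_reads(self):
        cfg = am.SimulationConfig(
            seed=21, n_otus=4, group_sizes={"O": 1}, replicates=2,
            library_mean=40, library_range=(20, 60),
            richness_mean={"O": 4}, richness_sd=0,
        )
        out = []
        for _ in range(2):
            study = am.simulate_study(cfg)
            reads = am.simulate_reads(study.references, study.truth, cfg)
            out.append(
                [
                    (s, r.id, r.bases, tuple(r.quals))
                    for s in sorted(reads)
                    for r in reads[s]
                ]
            )
        assert out[0] == out[1]


class TestCohort:
    def test_default_group_sizes_give_101_rows(self):
        meta, nutrients = am.simulate_cohort(am.SimulationConfig(seed=1))
        assert len(meta) == 101
        assert meta["group"].value_counts().to_dict() == {"O": 43, "V": 32, "VG": 26}
        assert nutrients.shape == (101, 76)

    def test_null_nutrients_reject_at_nominal_rate(self):
        # no planted effects: per-nutrient Kruskal-Wallis is a null test
        rejections = total = 0
        for seed in range(3):
            cfg = am.SimulationConfig(seed=seed, planted_nutrient_effects=False)
            meta, nutrients = am.simulate_cohort(cfg)
            for col in nutrients.columns:
                res = am.kruskal_wallis(nutrients[col], meta["group"])
                rejections += res["p"] < 0.05
                total += 1
        assert 0.01 <= rejections / total <= 0.10

    def test_planted_nutrients_dominate_group_separation(self):
        cfg = am.SimulationConfig(seed=2)
        meta, nutrients = am.simulate_cohort(cfg)
        h = {
            col: am.kruskal_wallis(nutrients[col], meta["group"])["H"]
            for col in nutrients.columns
        }
        ranked = sorted(h, key=h.get, reverse=True)
        planted = {"animal_proteins_g", "cholesterol_mg", "EPA_g", "DHA_g"}
        assert planted <= set(ranked[:8])
        assert ranked[0] in planted

    def test_no_planted_anthropometric_effect(self):
        cfg = am.SimulationConfig(seed=3)
        meta, _ = am.simulate_cohort(cfg)
        for col in ("age", "bmi", "bfm", "blm"):
            res = am.anova_tukey(meta[col], meta["group"])
            assert res.p > 0.001  # same distribution in every group


class TestCompositionsAndCounts:
    def test_compositions_sum_to_one_and_match_richness(self, small_study):
        for subject, comp in small_study.truth.compositions.items():
            assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)
            assert len(comp) == small_study.truth.richness[subject]

    def test_counts_follow_composition(self):
        cfg = am.SimulationConfig(
            seed=6, n_otus=12, group_sizes={"O": 1}, replicates=1,
            library_mean=50000, library_range=(50000, 50000),
            richness_mean={"O": 12}, richness_sd=0,
        )
        study = am.simulate_study(cfg)
        counts = am.simulate_counts(study.references, study.truth, cfg)
        subject = counts.columns[0]
        comp = study.truth.compositions[subject]
        expected = np.array([comp.get(o, 0.0) for o in counts.index]) * 50000
        keep = expected >= 5
        chi2 = ((counts[subject].to_numpy()[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = sps.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_replicates_share_composition(self, small_config, small_study):
        counts = am.simulate_counts(
            small_study.references, small_study.truth, small_config,
            per_replicate=True,
        )
        assert counts.shape[1] == 9 * 2
        assert {c.rsplit("_", 1)[0] for c in counts.columns} == set(
            small_study.metadata.index
        )
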