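"""Motif counting, densities, quartile summaries, category and structure stats."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whi3kit.io_formats import GeneModel
from whi3kit.motif_stats import (
    ParsTrack,
    assign_quartiles,
    category_enrichment,
    count_motif,
    density_table,
    find_motif,
    local_max_density,
    motif_density,
    pars_metaprofile,
    quartile_response_summary,
    utr3_presence_fraction,
)
from whi3kit.synthetic_data import (
    SimulationConfig,
    generate_counts,
    generate_pars_tracks,
    generate_ripchip,
)
from whi3kit.translation_profiling import compute_rpkm


class TestCountMotif:
    @pytest.mark.parametrize(
        "seq,motif,expected",
        [
            ("GCAUGCAU", "GCAU", 2),
            ("AUUUUAUUUUA", "AUUUUA", 2),  # overlapping starts at 0 and 5
            ("CCCC", "GCAU", 0),
            ("GCA", "GCAU", 0),  # motif longer than sequence
        ],
    )
    def test_examples(self, seq, motif, expected):
        assert count_motif(seq, motif) == expected

    def test_non_overlapping_mode(self):
        assert count_motif("AUUUUAUUUUA", "AUUUUA", allow_overlap=False) == 1

    @given(
        st.text(alphabet="ACGUN", min_size=0, max_size=50),
        st.text(alphabet="ACGU", min_size=1, max_size=4),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_equals_brute_force_position_scan(self, seq, motif):
        brute = sum(
            1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif
        )
        assert count_motif(seq, motif) == brute

    def test_density_invariant_under_self_concatenation(self):
        # junction chosen so no new occurrence spans it
        seq = "GCAUCCAAGGCAUCC"
        g1 = GeneModel("g", seq, 2, len(seq) - 4, 2)
        g2 = GeneModel("g", seq * 2, 2, 2 * len(seq) - 4, 2)
        assert motif_density(g1, "GCAU").density == pytest.approx(
            motif_density(g2, "GCAU").density
        )


class TestLocalMax:
    def test_cluster_in_first_window(self):
        seq = ["C"] * 600
        for p in (0, 50, 100, 150, 200):
            seq[p : p + 4] = "GCAU"
        seq[590:594] = "GCAU"
        assert local_max_density("".join(seq), "GCAU", window=300) == 5

    def test_uniform_spacing_one_per_100nt(self):
        seq = ["C"] * 1000
        for p in range(0, 1000, 100):
            seq[p : p + 4] = "GCAU"
        assert local_max_density("".join(seq), "GCAU", window=300) == 3

    def test_window_longer_than_sequence_gives_total(self):
        seq = "GCAU" + "C" * 200 + "GCAU" + "C" * 292
        assert local_max_density(seq, "GCAU", window=10**6) == 2

    def test_window_shorter_than_motif_errors(self):
        with pytest.raises(ValueError):
            local_max_density("GCAU", "GCAU", window=3)


class TestMotifDensity:
    def test_density_per_kb(self):
        seq = ["C"] * 2000
        for i in range(8):
            seq[i * 250 : i * 250 + 4] = "GCAU"
        g = GeneModel("g", "".join(seq), 200, 1600, 200)
        prof = motif_density(g, "GCAU")
        assert prof.count == 8 and prof.density == pytest.approx(4.0)

    def test_boundary_motif_assigned_by_start_position(self):
        # motif starts 2 nt before the UTR5/ORF boundary
        seq = "C" * 8 + "GCAU" + "C" * 8
        g = GeneModel("g", seq, 10, 8, 2)
        prof = motif_density(g, "GCAU")
        assert prof.region_counts == {"utr5": 1, "orf": 0, "utr3": 0}
        assert sum(prof.region_counts.values()) == prof.count


class TestQuartiles:
    def test_even_split_of_eight(self):
        vals = {f"g{i}": float(i) for i in range(1, 9)}
        q = assign_quartiles(vals)
        assert {g for g, lab in q.items() if lab == "Q1"} == {"g1", "g2"}
        assert {g for g, lab in q.items() if lab == "Q4"} == {"g7", "g8"}

    def test_largest_remainder_sizes_for_ten(self):
        vals = {f"g{i:02d}": float(i) for i in range(10)}
        q = assign_quartiles(vals)
        sizes = [sum(1 for lab in q.values() if lab == f"Q{i}") for i in (1, 2, 3, 4)]
        assert sizes == [3, 3, 2, 2]

    def test_all_equal_values_split_by_gene_id(self):
        vals = {g: 1.0 for g in "abcd"}
        q = assign_quartiles(vals)
        assert q == {"a": "Q1", "b": "Q2", "c": "Q3", "d": "Q4"}

    def test_fewer_than_four_genes_errors(self):
        with pytest.raises(ValueError):
            assign_quartiles({"a": 1.0, "b": 2.0, "c": 3.0})


def _rna_fold_changes(cfg, genes):
    tables = generate_counts(cfg, genes)
    lengths = {g: genes[g].orf_len for g in genes}
    wt = compute_rpkm(tables["rna_wt"], lengths)
    mut = compute_rpkm(tables["rna_mut"], lengths)
    common = wt.index.intersection(mut.index)
    return dict(np.log2(mut.loc[common] / wt.loc[common]))


class TestQuartileResponse:
    def test_pooled_quartile_means_reproduce_the_global_mean(self):
        rng = np.random.default_rng(0)
        fc = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=37))}
        q = assign_quartiles({g: rng.normal() for g in fc})
        summ = quartile_response_summary(fc, q, seed=0)
        pooled = (summ["mean_log2"] * summ["n"]).sum() / summ["n"].sum()
        assert pooled == pytest.approx(np.mean(list(fc.values())))

    def test_planted_density_effect_gives_monotone_quartile_means(self, genes):
        cfg = SimulationConfig(seed=3)
        fc = _rna_fold_changes(cfg, genes)
        dens = density_table(genes, "GCAU")["density"]
        q = assign_quartiles(dict(dens))
        means = quartile_response_summary(fc, q, seed=3)["mean_log2"]
        assert list(means) == sorted(means)  # Q1 < Q2 < Q3 < Q4

    def test_control_motif_shows_no_comparable_trend(self, genes):
        cfg = SimulationConfig(seed=3)
        fc = _rna_fold_changes(cfg, genes)
        motif_means = quartile_response_summary(
            fc, assign_quartiles(dict(density_table(genes, "GCAU")["density"])), seed=3
        )["mean_log2"]
        ctrl_means = quartile_response_summary(
            fc, assign_quartiles(dict(density_table(genes, "CGUA")["density"])), seed=3
        )["mean_log2"]
        assert np.ptp(ctrl_means) < 0.25 * np.ptp(motif_means)

    def test_shuffled_labels_flatten_the_trend(self, genes):
        cfg = SimulationConfig(seed=3)
        fc = _rna_fold_changes(cfg, genes)
        dens = density_table(genes, "GCAU")["density"]
        q = assign_quartiles(dict(dens))
        rng = np.random.default_rng(12)
        keys = list(fc)
        shuffled = dict(zip(keys, rng.permutation([fc[g] for g in keys])))
        real = np.ptp(quartile_response_summary(fc, q, seed=3)["mean_log2"])
        null = np.ptp(quartile_response_summary(shuffled, q, seed=3)["mean_log2"])
        assert null < 0.5 * real

    def test_empty_quartile_errors(self):
        with pytest.raises(ValueError):
            quartile_response_summary({"a": 1.0}, {"a": "Q1"})


class TestUtr3Presence:
    def test_one_of_four(self):
        genes = {}
        for i, utr3 in enumerate(["CCCCCCCC", "AUUUUACC", "CCCCCCCC", "CCCCCCCC"]):
            seq = "G" * 10 + utr3
            genes[f"g{i}"] = GeneModel(f"g{i}", seq, 0, 10, 8)
        assert utr3_presence_fraction(genes, "AUUUUA", genes.keys()) == 0.25

    def test_absent_motif_gives_zero(self):
        g = GeneModel("g", "G" * 10 + "CCCC", 0, 10, 4)
        assert utr3_presence_fraction({"g": g}, "AUUUUA", ["g"]) == 0.0

    def test_orf_occurrence_does_not_count(self):
        g = GeneModel("g", "AUUUUA" + "G" * 6 + "CCCC", 0, 12, 4)
        assert utr3_presence_fraction({"g": g}, "AUUUUA", ["g"]) == 0.0

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            utr3_presence_fraction({}, "AUUUUA", [])


class TestCategoryEnrichment:
    def test_zero_hits_gives_p_one(self):
        assert category_enrichment(0, 10, 0.3) == pytest.approx(1.0)

    def test_all_hits_fair_coin(self):
        assert category_enrichment(10, 10, 0.5) == pytest.approx(2.0**-10)

    def test_against_exact_tail_oracle(self):
        # published membrane-annotation example: 91 of 262 at background 21.3%
        k, n, f = 91, 262, 0.213
        fr = Fraction(213, 1000)
        exact = sum(
            math.comb(n, i) * fr**i * (1 - fr) ** (n - i) for i in range(k, n + 1)
        )
        assert category_enrichment(k, n, f) == pytest.approx(float(exact), rel=1e-9)

    def test_invalid_bounds_error(self):
        with pytest.raises(ValueError):
            category_enrichment(5, 3, 0.2)
        with pytest.raises(ValueError):
            category_enrichment(1, 3, 1.5)


class TestParsMetaprofile:
    def test_constant_tracks_give_flat_profile(self):
        tracks = {"g": ParsTrack("g", tuple([1.0] * 200))}
        prof = pars_metaprofile(tracks, [("g", 100)], motif_len=4, groups={"g": "t"})
        assert np.allclose(prof["t"], 1.0)
        assert prof["t"].size == 104

    def test_occurrence_without_full_flank_is_dropped(self):
        tracks = {"g": ParsTrack("g", tuple([1.0] * 200))}
        with pytest.raises(ValueError):
            # only occurrence sits 10 nt from the 5' end: dropped, group empty
            pars_metaprofile(tracks, [("g", 10)], motif_len=4, groups={"g": "t"})

    def test_planted_dip_appears_only_in_target_group(self, cfg, genes):
        _, truth = generate_ripchip(cfg, genes)
        tracks = generate_pars_tracks(cfg, genes, target_genes=truth)
        occurrences = [
            (gid, s)
            for gid, m in genes.items()
            for s in find_motif(m.sequence, "GCAU")
        ]
        groups = {g: ("target" if g in set(truth) else "non") for g in genes}
        prof = pars_metaprofile(tracks, occurrences, motif_len=4, groups=groups)
        assert prof["target"].min() < 0.3  # dip of depth ~1 at the motif centre
        assert prof["non"].min() > 0.9
        centre = prof["target"][48:56].mean()
        edges = np.concatenate([prof["target"][:10], prof["target"][-10:]]).mean()
        assert centre < edges - 0.5
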