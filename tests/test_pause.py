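"""Pause-score and di-codon statistics tests, including brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ribopause as rp
from ribopause.pause import DensityProfile, DicodonScoreTable
from ribopause.simulate import SENSE_CODONS

from conftest import pipeline_core


def make_calls(tid, codon_indices, cls="short"):
    return pd.DataFrame(
        {
            "transcript_id": tid,
            "length_class": cls,
            "a_codon": codon_indices,
            "in_cds": True,
        }
    )


def make_orf(tid, codons):
    return rp.OrfRecord(tid, "".join(codons), 0, 3 * len(codons))


class TestDensityProfiles:
    def test_counts_conserve_in_cds_calls(self):
        rng = np.random.default_rng(0)
        orf = make_orf("T", ["AAA"] * 30)
        calls = make_calls("T", rng.integers(0, 30, 100))
        profiles, _ = rp.build_density_profiles(calls, [orf])
        assert profiles[("T", "short")].counts.sum() == 100

    def test_uniform_two_calls_per_interior_codon(self):
        orf = make_orf("T", ["AAA"] * 30)
        calls = make_calls("T", np.repeat(np.arange(5, 25), 2))
        profiles, _ = rp.build_density_profiles(calls, [orf])
        assert profiles[("T", "short")].interior_mean == 2.0

    def test_interior_mean_matches_hand_sum_on_crafted_profile(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 9, 20)
        prof = DensityProfile("T", "short", counts.astype(float))
        assert prof.interior_mean == pytest.approx(sum(counts[5:15]) / 10)

    def test_short_orfs_without_interior_are_reported(self):
        orfs = [make_orf("tiny", ["AAA"] * 10), make_orf("ok", ["AAA"] * 11)]
        profiles, excluded = rp.build_density_profiles(make_calls("ok", [5]), orfs)
        assert excluded == ["tiny"]
        assert ("tiny", "short") not in profiles and ("ok", "short") in profiles


class TestFilter:
    def test_boundary_density_is_retained_inclusive(self):
        counts = np.zeros(30)
        counts[5:25] = 0.5  # interior mean exactly 0.5
        keep = rp.filter_orfs({("T", "short"): DensityProfile("T", "short", counts)})
        assert ("T", "short") in keep

    def test_just_below_boundary_is_dropped(self):
        counts = np.zeros(30)
        counts[5:25] = 0.49
        keep = rp.filter_orfs({("T", "short"): DensityProfile("T", "short", counts)})
        assert keep == {}

    def test_matches_list_comprehension_oracle_on_toy_set(self):
        rng = np.random.default_rng(2)
        profiles = {
            (f"T{i}", "short"): DensityProfile(
                f"T{i}", "short", rng.poisson(0.5, 40).astype(float)
            )
            for i in range(10)
        }
        oracle = {
            k for k, p in profiles.items() if p.counts[5:35].mean() >= 0.5
        }
        assert set(rp.filter_orfs(profiles)) == oracle
        assert 0 < len(oracle) < 10  # the toy set straddles the boundary


class TestPauseScores:
    def test_uniform_profile_scores_one_everywhere(self):
        prof = DensityProfile("T", "short", np.full(25, 3.0))
        assert np.allclose(rp.pause_scores(prof)["score"], 1.0)

    def test_single_loaded_codon_scores_interior_length(self):
        counts = np.zeros(30)
        counts[12] = 60.0
        prof = DensityProfile("T", "short", counts)
        scores = rp.pause_scores(prof).set_index("codon_index")["score"]
        assert scores.loc[12] == 20.0  # L = 20 interior codons
        assert (scores.drop(12) == 0).all()

    def test_matches_two_line_oracle_on_random_profile(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, 40).astype(float)
        prof = DensityProfile("T", "short", counts)
        interior = counts[5:35]
        oracle = interior / interior.mean()
        assert np.allclose(rp.pause_scores(prof)["score"], oracle, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(2.0, 40).astype(float) + 1
        s1 = rp.pause_scores(DensityProfile("T", "short", counts))["score"]
        s2 = rp.pause_scores(DensityProfile("T", "short", 7.3 * counts))["score"]
        assert np.allclose(s1, s2)

    def test_grand_mean_is_exactly_one(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3.0, 50).astype(float)
        scores = rp.pause_scores(DensityProfile("T", "short", counts))["score"]
        assert scores.mean() == pytest.approx(1.0, abs=1e-12)


class TestDicodonTable:
    def test_mean_of_two_occurrences(self):
        occ = pd.DataFrame(
            {
                "p_codon": ["CGA", "CGA"],
                "a_codon": ["CGA", "CGA"],
                "length_class": "short",
                "transcript_id": "T",
                "codon_index": [6, 9],
                "score": [2.0, 4.0],
            }
        )
        summary = DicodonScoreTable(occ).summary(min_occurrences=1)
        assert summary["mean"].iloc[0] == 3.0 and summary["n"].iloc[0] == 2

    def test_absent_pairs_are_not_zero_filled(self):
        orf = make_orf("T", ["AAA"] * 6 + ["CCC", "GGG"] + ["AAA"] * 6)
        calls = make_calls("T", np.arange(5, 9).repeat(2))
        _, _, retained = (
            None,
            None,
            rp.filter_orfs(rp.build_density_profiles(calls, [orf])[0], 0.0),
        )
        retained = {k: v for k, v in retained.items() if v.interior_mean > 0}
        table = rp.dicodon_scores(retained, [orf])
        pairs = set(zip(table.occurrences["p_codon"], table.occurrences["a_codon"]))
        assert ("CCC", "GGG") in pairs and ("GGG", "CCC") not in pairs

    def test_rank_tie_break_by_n_then_lexicographic(self):
        rows = []
        for pair, mean, n in [("AAA", 3.0, 2), ("CCC", 2.0, 5), ("GGG", 2.0, 9)]:
            rows += [
                {
                    "p_codon": pair,
                    "a_codon": pair,
                    "length_class": "short",
                    "transcript_id": "T",
                    "codon_index": 6,
                    "score": mean,
                }
            ] * n
        table = DicodonScoreTable(pd.DataFrame(rows))
        ranked = table.rank("short", top_n=10, min_occurrences=1)
        assert list(ranked["p_codon"]) == ["AAA", "GGG", "CCC"]

    def test_top_n_zero_returns_empty(self):
        table = DicodonScoreTable(
            pd.DataFrame(
                {
                    "p_codon": ["AAA"],
                    "a_codon": ["AAA"],
                    "length_class": ["short"],
                    "transcript_id": ["T"],
                    "codon_index": [6],
                    "score": [1.0],
                }
            )
        )
        assert table.rank("short", top_n=0, min_occurrences=1).empty


def brute_force_dicodon_table(orfs, reads, edge=5, min_density=0.5):
    """Independent reference: loop over reads with no intermediate structures."""
    from collections import defaultdict

    offsets = {20: 15, 21: 15, 22: 16, 27: 14, 28: 15, 29: 16}
    out = {}
    for cls, lengths in (("short", (20, 21, 22)), ("long", (27, 28, 29))):
        per_pair = defaultdict(list)
        for orf in orfs:
            cc = orf.codon_count
            if cc <= 2 * edge:
                continue
            counts = [0] * cc
            for row in reads.itertuples(index=False):
                if row.transcript_id != orf.transcript_id or row.length not in lengths:
                    continue
                k = (row.pos5 + offsets[row.length] - orf.cds_start) // 3
                if 0 <= k < cc:
                    counts[k] += 1
            interior = counts[edge : cc - edge]
            mean = sum(interior) / len(interior)
            if mean < min_density:
                continue
            codons = orf.codons()
            for i in range(edge, cc - edge):
                if i >= 1:
                    per_pair[(codons[i - 1], codons[i], cls)].append(counts[i] / mean)
        for key, scores in per_pair.items():
            out[key] = (len(scores), sum(scores) / len(scores))
    return out


class TestOracleEquivalence:
    def test_full_table_matches_read_loop_reference_on_toy_input(self):
        cfg = rp.SimulationConfig(
            n_transcripts=8,
            codon_count_range=(40, 70),
            mean_reads_per_codon=1.2,
            stall_specs=[rp.StallSpec("CGA", "CGA", enrichment_short=10.0)],
            planted_per_spec=8,
            duplicate_fraction=0.1,
            seed=21,
        )
        tx = rp.simulate_transcriptome(cfg)
        sim = rp.simulate_footprints(tx, cfg)
        reads = rp.dedup(sim.reads)
        _, _, retained = pipeline_core(sim.reads, tx.orfs)
        table = rp.dicodon_scores(retained, tx.orfs).summary(min_occurrences=1)
        oracle = brute_force_dicodon_table(tx.orfs, reads)
        ours = {
            (r.p_codon, r.a_codon, r.length_class): (r.n, r.mean)
            for r in table.itertuples(index=False)
        }
        assert set(ours) == set(oracle)
        for key, (n, mean) in oracle.items():
            assert ours[key][0] == n
            assert ours[key][1] == pytest.approx(mean, abs=1e-12)


class TestParameterRecovery:
    def test_three_planted_stalls_recovered_in_injected_order(self, recovery_tables):
        """The 50x pair tops the short-footprint ranking and the three
        planted enrichments come back in their injected order, every seed."""
        from conftest import RECOVERY_SPECS

        for table in recovery_tables:
            summary = table.summary(min_occurrences=1).set_index(
                ["p_codon", "a_codon", "length_class"]
            )
            ranked = table.rank("short", top_n=3)
            assert (ranked.iloc[0]["p_codon"], ranked.iloc[0]["a_codon"]) == ("CGA", "CGA")
            means = [
                summary.loc[(s.p_codon, s.a_codon, "short")]["mean"]
                for s in RECOVERY_SPECS
            ]
            assert means == sorted(means, reverse=True)

    def test_long_class_unaffected_by_short_only_stall(self, stall_sim):
        tx, sim, _ = stall_sim
        _, _, retained = pipeline_core(sim.reads, tx.orfs)
        summary = rp.dicodon_scores(retained, tx.orfs).summary(min_occurrences=1)
        row = summary[
            (summary.p_codon == "CGA")
            & (summary.a_codon == "CGA")
            & (summary.length_class == "long")
        ]
        assert row["mean"].iloc[0] == pytest.approx(1.0, abs=0.4)
        row_s = summary[
            (summary.p_codon == "CGA")
            & (summary.a_codon == "CGA")
            & (summary.length_class == "short")
        ]
        assert row_s["mean"].iloc[0] > 10
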