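"""Preprocessing: AscI filter/trim, collapse+match, size factors, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import specs
from specs.library_design import ASCI_SITE
from specs.ngs_preprocess import (
    CountMatrix,
    PreprocessError,
    collapse_and_count,
    count_samples,
    filter_and_trim,
    match_sanger,
    size_factors,
)


class TestFilterAndTrim:
    def test_read_trimmed_at_asci_5prime_edge(self):
        kept, report = filter_and_trim(["ACGTACGT" + ASCI_SITE + "TTTT"])
        assert kept == {"ACGTACGT": 1}
        assert report == {"kept": 1, "dropped": 0, "unique": 1}

    def test_read_without_site_dropped(self):
        kept, report = filter_and_trim(["ACGTACGTTTTT"])
        assert not kept and report["dropped"] == 1

    def test_toy_file_counts(self, tmp_path):
        reads = ([f"SEQ{i}" * 3 + ASCI_SITE + "AA" for i in range(7)]
                 + ["TTTTTTTTTTTT"] * 3)
        path = tmp_path / "toy.fastq"
        with open(path, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        _, report = filter_and_trim(path)
        assert (report["kept"], report["dropped"]) == (7, 3)

    def test_malformed_fastq_reports_record_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\nnot-a-header\nACGT\n+\nIIII\n")
        with pytest.raises(PreprocessError, match="record 2"):
            filter_and_trim(path)


class TestCollapseAndCount:
    def test_exact_matches_recover_multiplicities(self, toy_library):
        regions = [c.variable_region for c in toy_library.constructs[:3]]
        trimmed = regions * 2 + regions[:1] * 3
        counts, report = collapse_and_count(trimmed, toy_library)
        assert counts[toy_library.constructs[0].construct_id] == 5
        assert counts[toy_library.constructs[1].construct_id] == 2
        assert report["unassigned"] == 0

    def test_single_mismatch_assigned_to_nearest(self, toy_library):
        c = toy_library.constructs[0]
        seq = list(c.variable_region)
        seq[5] = "A" if seq[5] != "A" else "C"
        counts, _ = collapse_and_count(["".join(seq)], toy_library)
        assert counts[c.construct_id] == 1

    def test_equidistant_sequence_unassigned(self):
        # two references at Hamming distance 2 from each other; a hybrid read
        # sits at distance 1 from both
        motifs = [
            specs.MotifMatrix("m1", "t1", np.eye(4)[[0, 0, 0, 0, 0, 0]].astype(float)),
            specs.MotifMatrix("m2", "t2", np.eye(4)[[1, 0, 0, 0, 0, 1]].astype(float)),
        ]
        lib = specs.build_library(motifs, seed=0)
        r1 = lib.constructs[0].variable_region  # (AAAAAA+spacer) repeats
        (r2,) = [c.variable_region for c in lib
                 if c.source_motif_id == "m2" and c.strand == "forward"]
        diff = [i for i, (a, b) in enumerate(zip(r1, r2)) if a != b]
        assert len(diff) % 2 == 0
        # flip exactly half the differing sites: equidistant from both refs
        hybrid = list(r1)
        for i in diff[: len(diff) // 2]:
            hybrid[i] = r2[i]
        _, report = collapse_and_count(["".join(hybrid)], lib,
                                       max_mismatches=len(diff))
        assert report["unassigned"] == 1

    def test_matches_bruteforce_hamming_scan(self, toy_library):
        """Assignment agrees with an all-pairs naive Hamming oracle."""
        rng = np.random.default_rng(17)
        regions = {c.construct_id: c.variable_region for c in toy_library}
        reads = []
        for c in toy_library:
            seq = list(c.variable_region)
            for pos in rng.choice(len(seq), size=2, replace=False):
                seq[int(pos)] = "ACGT"[rng.integers(4)]
            reads.append("".join(seq))
        counts, _ = collapse_and_count(reads, toy_library, max_mismatches=2)

        def oracle(read):
            dists = {}
            for cid, region in regions.items():
                if len(region) != len(read):
                    continue
                dists[cid] = sum(a != b for a, b in zip(read, region))
            best = min(dists.values())
            hits = [cid for cid, d in dists.items() if d == best]
            return hits[0] if best <= 2 and len(hits) == 1 else None

        expected = pd.Series(0, index=counts.index)
        for read in reads:
            cid = oracle(read)
            if cid is not None:
                expected[cid] += 1
        pd.testing.assert_series_equal(counts, expected, check_names=False,
                                       check_dtype=False)

    def test_edit_mode_accepts_single_deletion(self, toy_library):
        c = toy_library.constructs[0]
        seq = c.variable_region[:10] + c.variable_region[11:]
        counts, _ = collapse_and_count([seq], toy_library, max_mismatches=2,
                                       mode="edit")
        assert counts[c.construct_id] == 1

    def test_empty_library_rejected(self):
        from specs.library_design import LibraryReference
        with pytest.raises(PreprocessError):
            collapse_and_count(["ACGT"], LibraryReference([]))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame({"s1": [5, 9, 2], "s2": [5, 9, 2]})
        np.testing.assert_allclose(size_factors(df), [1.0, 1.0])

    def test_hand_computed_median_of_ratios(self):
        df = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        np.testing.assert_allclose(size_factors(df),
                                   [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_agrees_with_deseq2_reference_implementation(self):
        """Cross-check against pydeseq2's median-of-ratios on random counts."""
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(23)
        raw = pd.DataFrame(rng.integers(1, 500, size=(40, 6)),
                           columns=[f"s{i}" for i in range(6)])
        ours = size_factors(raw)
        _, theirs = deseq2_norm(raw.T)  # pydeseq2 expects samples x genes
        np.testing.assert_allclose(ours.to_numpy(), theirs, rtol=1e-9)

    @given(st.floats(min_value=0.1, max_value=50))
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(5)
        raw = pd.DataFrame(rng.integers(1, 100, size=(20, 3)).astype(float),
                           columns=list("xyz"))
        base = size_factors(raw)
        scaled = raw.copy()
        scaled["y"] *= c
        new = size_factors(scaled)
        # the scaled sample's factor grows by c relative to the unscaled ones,
        # up to the common geometric-mean renormalization
        np.testing.assert_allclose((new["y"] / new["x"]),
                                   c * base["y"] / base["x"], rtol=1e-9)

    def test_all_zero_row_structure_raises_with_hint(self):
        df = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(PreprocessError, match="pseudocount"):
            size_factors(df)


def _count_matrix(raw_by_sample, states):
    raw = pd.DataFrame(raw_by_sample)
    raw.index = [f"P{i}" for i in range(len(raw))]
    samples = pd.DataFrame({
        "sample_id": list(raw.columns),
        "state": [states[s] for s in raw.columns],
        "replicate": [s.split("_")[1] for s in raw.columns],
        "bin": ["negative"] * len(raw.columns),
    }).set_index("sample_id")
    return CountMatrix(raw=raw, samples=samples)


class TestReplicateFilter:
    def make(self):
        # 5 constructs engineered so exactly 3 pass (nonzero in >=2 reps of
        # both states): P0, P1 pass; P2 misses state B entirely; P3 has one
        # replicate in A; P4 passes.
        data = {
            "A_r1_neg": [3, 1, 4, 2, 9],
            "A_r2_neg": [5, 2, 6, 0, 8],
            "B_r1_neg": [7, 3, 0, 5, 1],
            "B_r2_neg": [2, 4, 0, 6, 3],
        }
        states = {k: k.split("_")[0] for k in data}
        return _count_matrix(data, states)

    def test_engineered_fixture_retains_three(self):
        cm = self.make()
        filtered, report = cm.replicate_filter()
        assert report == {"retained": 3, "dropped": 2}
        assert list(filtered.raw.index) == ["P0", "P1", "P4"]

    def test_single_replicate_state_rejected(self):
        raw = pd.DataFrame({"A_r1_neg": [1], "B_r1_neg": [1], "B_r2_neg": [1]})
        raw.index = ["P0"]
        samples = pd.DataFrame({
            "sample_id": list(raw.columns),
            "state": [c.split("_")[0] for c in raw.columns],
            "replicate": [c.split("_")[1] for c in raw.columns],
            "bin": ["negative"] * 3,
        }).set_index("sample_id")
        cm = CountMatrix(raw=raw, samples=samples)
        with pytest.raises(PreprocessError, match="replicate"):
            cm.replicate_filter()


class TestMatchSanger:
    def test_exact_region_intact(self, toy_library):
        c = toy_library.constructs[2]
        res = match_sanger("TT" + c.variable_region + "ACGT", toy_library)
        assert res["status"] == "intact"
        assert res["construct_id"] == c.construct_id

    def test_one_substitution_mutated_with_one_edit(self, toy_library):
        c = toy_library.constructs[2]
        seq = list(c.variable_region)
        seq[7] = "A" if seq[7] != "A" else "G"
        res = match_sanger("".join(seq), toy_library)
        assert res["status"] == "mutated"
        assert res["construct_id"] == c.construct_id
        assert res["edits"] == 1

    def test_random_sequence_unidentifiable(self, toy_library):
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), size=150))
        # verify the fixture is genuinely far from every construct
        dists = [sum(a != b for a, b in zip(seq, c.variable_region))
                 for c in toy_library if len(c.variable_region) <= len(seq)]
        assert min(dists) > 10
        assert match_sanger(seq, toy_library)["status"] == "unidentifiable"

    def test_empty_sequence_rejected(self, toy_library):
        with pytest.raises(ValueError):
            match_sanger("", toy_library)


class TestRoundTrip:
    def test_error_free_reads_reproduce_simulated_counts(self, toy_library, tmp_path):
        truth = specs.make_ground_truth(toy_library.construct_ids(), seed=41)
        screen = specs.simulate_screen(truth, depth=5000, n_bio=1, n_tech=1,
                                       seed=42)
        paths = specs.emit_reads(screen, toy_library, tmp_path, error_rate=0.0,
                                 junk_fraction=0.0, seed=43)
        counts, _ = count_samples({p.stem: p for p in paths}, toy_library)
        expected = screen.flat_counts()
        pd.testing.assert_frame_equal(counts[expected.columns].loc[expected.index],
                                      expected)

    def test_common_scaling_passes_straight_through_normalization(self, small_screen):
        """Scaling every sample by c leaves size factors unchanged, so the
        normalized counts carry exactly that factor of c and nothing else."""
        cm = CountMatrix.from_screen(small_screen).normalize(pseudocount=0.5)
        scaled = CountMatrix(raw=cm.raw * 4, samples=cm.samples.copy())
        scaled.normalize(pseudocount=2.0)  # pseudocount on the same scale
        pd.testing.assert_series_equal(scaled.factors, cm.factors,
                                       check_exact=False, rtol=1e-9)
        pd.testing.assert_frame_equal(scaled.normalized / 4, cm.normalized,
                                      check_exact=False, rtol=1e-9)
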