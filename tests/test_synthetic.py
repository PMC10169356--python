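"""Billboard dataset generator: sampling contracts, reproducibility, round-trips."""

import numpy as np
import pytest

from simplexgrad.evaluation import information_content
from simplexgrad.motifs import MotifLibrary, PFM, load_pfms, pfm_from_consensus
from simplexgrad.synthetic import (
    generate_dataset,
    read_dataset,
    sample_sequence,
    write_dataset,
)


class TestMotifLibrary:
    def test_default_pools(self, library):
        assert len(library.core_motifs) == 10  # 5 factors + reverse complements
        assert len(library.background_motifs) == 100
        names = {m.name for m in library.core_motifs}
        assert {"CEBPB", "GABPA", "MAX", "SP1", "YY1"} <= {n.replace("_rc", "") for n in names}
        assert not set(library.core_motifs) & set(library.background_motifs)

    def test_pfm_columns_are_probabilities(self, library):
        for pfm in library.negative_pool:
            np.testing.assert_allclose(pfm.probs.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(pfm.probs >= 0)

    def test_reverse_complement_involution(self, library):
        pfm = library.core_motifs[0]
        rc2 = pfm.reverse_complement().reverse_complement()
        np.testing.assert_array_equal(rc2.probs, pfm.probs)

    def test_reverse_complement_swaps_bases(self):
        pfm = pfm_from_consensus("X", "A")
        rc = pfm.reverse_complement()
        # A column becomes T column
        assert rc.probs[0, 3] == pfm.probs[0, 0]

    def test_core_motifs_are_informative(self, library):
        for pfm in library.core_motifs:
            info = information_content(pfm.probs)
            assert info.max() > 1.0  # strong core positions
            assert np.all(info > 0.1)  # every column counts as a true-positive position


class TestPFMParsing:
    def test_jaspar_roundtrip(self, tmp_path):
        text = (
            ">MA0000.1 TESTA\n"
            "A [ 10  0  5 ]\n"
            "C [  0 20  5 ]\n"
            "G [  5  0  5 ]\n"
            "T [  5  0  5 ]\n"
        )
        (tmp_path / "m.jaspar").write_text(text)
        pfms = load_pfms(tmp_path / "m.jaspar")
        assert len(pfms) == 1 and pfms[0].name == "TESTA" and pfms[0].width == 3
        np.testing.assert_allclose(pfms[0].probs[1], [0, 1, 0, 0])

    def test_meme_format(self, tmp_path):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF m1\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 20\n"
            "0.25 0.25 0.25 0.25\n"
            "0.10 0.20 0.30 0.40\n"
        )
        (tmp_path / "m.meme").write_text(text)
        pfms = load_pfms(tmp_path / "m.meme")
        assert pfms[0].width == 2
        np.testing.assert_allclose(pfms[0].probs[1], [0.1, 0.2, 0.3, 0.4])

    def test_empty_input_rejected(self, tmp_path):
        (tmp_path / "x.txt").write_text("nothing here\n")
        with pytest.raises(ValueError):
            load_pfms(tmp_path / "x.txt")


class TestSampleSequence:
    def test_positive_class_contract(self, library):
        core_names = {m.name for m in library.core_motifs}
        for seed in range(10):
            s = sample_sequence(1, library, rng_seed=seed)
            assert 3 <= len(s.motif_placements) <= 5
            assert all(name in core_names for name, _, _ in s.motif_placements)

    def test_ground_truth_structure(self, library):
        s = sample_sequence(0, library, rng_seed=3)
        covered = np.zeros(200, bool)
        for name, start, end in s.motif_placements:
            covered[start:end] = True
            np.testing.assert_array_equal(
                s.ground_truth.probs[start:end], library.by_name[name].probs
            )
        np.testing.assert_array_equal(s.ground_truth.probs[~covered], 0.25)
        assert np.all(information_content(s.ground_truth.probs)[~covered] == 0)

    def test_placements_do_not_overlap(self, library):
        for seed in range(20):
            s = sample_sequence(1, library, rng_seed=seed)
            spans = sorted((a, b) for _, a, b in s.motif_placements)
            assert all(b1 <= a2 for (_, b1), (a2, _) in zip(spans, spans[1:]))

    def test_deterministic_given_seed(self, library):
        a = sample_sequence(1, library, rng_seed=42)
        b = sample_sequence(1, library, rng_seed=42)
        np.testing.assert_array_equal(a.onehot, b.onehot)
        assert a.motif_placements == b.motif_placements

    def test_impossible_placement_raises(self, library):
        with pytest.raises((RuntimeError, ValueError)):
            sample_sequence(1, library, length=25, rng_seed=0)

    def test_invalid_label(self, library):
        with pytest.raises(ValueError):
            sample_sequence(2, library)


class TestGenerateDataset:
    def test_split_sizes_and_balance(self, tiny_dataset):
        n = sum(len(tiny_dataset.split(k)) for k in ("train", "valid", "test"))
        assert n == 600
        assert len(tiny_dataset.train) == 420 and len(tiny_dataset.valid) == 60
        for name in ("train", "valid", "test"):
            labels = [s.label for s in tiny_dataset.split(name)]
            assert abs(sum(labels) - (len(labels) - sum(labels))) <= 1

    def test_paper_scale_split_arithmetic(self):
        # n * fractions at the printed defaults: 14,000 / 2,000 / 4,000
        n, fr = 20_000, (0.7, 0.1, 0.2)
        per_class = n // 2
        sizes = [2 * int(round(per_class * f)) for f in fr]
        assert sizes == [14_000, 2_000, 4_000]

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            generate_dataset(n=11)
        with pytest.raises(ValueError):
            generate_dataset(n=10, fractions=(0.5, 0.2, 0.2))

    def test_splits_disjoint(self, tiny_dataset):
        ids = [s.sequence_id for k in ("train", "valid", "test") for s in tiny_dataset.split(k)]
        assert len(ids) == len(set(ids))

    def test_reproducible_from_seed(self, library):
        a = generate_dataset(n=20, library=library, seed=5)
        b = generate_dataset(n=20, library=library, seed=5)
        for k in ("train", "valid", "test"):
            for sa, sb in zip(a.split(k), b.split(k)):
                assert sa.sequence_id == sb.sequence_id
                np.testing.assert_array_equal(sa.onehot, sb.onehot)

    def test_background_positions_near_uniform(self, tiny_dataset):
        counts = np.zeros(4)
        for s in tiny_dataset.train:
            covered = np.zeros(200, bool)
            for _, a, b in s.motif_placements:
                covered[a:b] = True
            counts += s.onehot[~covered].sum(axis=0)
        freqs = counts / counts.sum()
        assert counts.sum() > 10_000
        np.testing.assert_allclose(freqs, 0.25, atol=0.01)

    def test_core_rate_in_negatives_matches_uniform_draws(self, library):
        """Expected core placements per negative = E[k] * 10/110 under uniform pool draws."""
        rng_seeds = range(400)
        core_names = {m.name for m in library.core_motifs}
        counts = [
            sum(
                1
                for name, _, _ in sample_sequence(0, library, rng_seed=s).motif_placements
                if name in core_names
            )
            for s in rng_seeds
        ]
        counts = np.asarray(counts, dtype=float)
        p = len(library.core_motifs) / len(library.negative_pool)
        expected = 4.0 * p  # E[k] = 4
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) <= 3 * se


class TestDatasetIO:
    def test_roundtrip_exact(self, library, tmp_path):
        splits = generate_dataset(n=30, library=library, seed=9)
        write_dataset(splits, tmp_path)
        back = read_dataset(tmp_path)
        assert back.fractions == splits.fractions and back.seed == splits.seed
        for k in ("train", "valid", "test"):
            for sa, sb in zip(splits.split(k), back.split(k)):
                assert sa.sequence_id == sb.sequence_id and sa.label == sb.label
                np.testing.assert_array_equal(sa.onehot, sb.onehot)
                np.testing.assert_array_equal(sa.ground_truth.probs, sb.ground_truth.probs)
                assert sorted(sa.motif_placements) == sorted(sb.motif_placements)

    def test_byte_identical_fasta_across_runs(self, library, tmp_path):
        for d in ("a", "b"):
            write_dataset(generate_dataset(n=10, library=library, seed=3), tmp_path / d)
        assert (tmp_path / "a" / "train.fa").read_bytes() == (tmp_path / "b" / "train.fa").read_bytes()

    def test_bed_widths_and_fasta_labels(self, library, tmp_path):
        splits = generate_dataset(n=10, library=library, seed=4)
        write_dataset(splits, tmp_path)
        from simplexgrad import io as sgio

        placements = sgio.read_bed(tmp_path / "train_motifs.bed")
        by_name = library.by_name
        for seq_id, entries in placements.items():
            for motif_id, start, end in entries:
                assert end - start == by_name[motif_id].width
        labels = {rid: lab for rid, lab, _ in sgio.read_fasta(tmp_path / "train.fa")}
        for s in splits.train:
            assert labels[s.sequence_id] == s.label
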