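import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ccpower as cp
from ccpower.genome import (
    ADDITIVE_MATRIX,
    N_STATES,
    STATE_LABELS,
    FounderProbTable,
    GenomeValidationError,
    MarkerMap,
)
from conftest import random_prob_table


def test_state_order_and_additive_matrix():
    assert STATE_LABELS[:8] == ("AA", "BB", "CC", "DD", "EE", "FF", "GG", "HH")
    assert STATE_LABELS[8] == "AB" and STATE_LABELS[-1] == "GH"
    A = ADDITIVE_MATRIX
    assert A.shape == (36, 8)
    assert np.all(A.sum(axis=1) == 2)
    # homozygous rows: a single 2; heterozygous rows: two 1s
    assert np.all(A[:8].max(axis=1) == 2)
    assert np.all((A[8:] == 1).sum(axis=1) == 2)


class TestCacheIO:
    def test_round_trip_and_count_conservation(self, tmp_path):
        table = random_prob_table(3, 10, seed=0, n_chroms=2)  # 2 chrom x 5 loci x 3 strains
        cp.save_genome_cache(table, tmp_path / "cache")
        loaded = cp.load_genome_cache(tmp_path / "cache")
        assert loaded.n_loci == 10 and loaded.n_strains == 3
        np.testing.assert_allclose(loaded.probs, table.probs, atol=1e-12)
        assert loaded.strain_ids == table.strain_ids
        assert list(loaded.markers.locus_ids) == list(table.markers.locus_ids)

    def test_missing_chromosome_file(self, tmp_path):
        table = random_prob_table(3, 10, seed=0, n_chroms=2)
        d = cp.save_genome_cache(table, tmp_path / "cache")
        (d / "chr2.csv").unlink()
        with pytest.raises(FileNotFoundError):
            cp.load_genome_cache(d)

    def test_bad_probability_row_rejected(self):
        table = random_prob_table(3, 4, seed=1)
        probs = table.probs.copy()
        probs[0, 0] *= 0.8  # row sums to 0.8
        with pytest.raises(GenomeValidationError, match="sums to"):
            FounderProbTable(table.strain_ids, table.markers, probs)

    def test_duplicate_locus_ids_rejected(self):
        df = pd.DataFrame(
            {"locus_id": ["a", "a"], "chromosome": ["1", "1"], "position_mb": [1.0, 2.0]}
        )
        with pytest.raises(GenomeValidationError, match="duplicated"):
            MarkerMap(df)


class TestReduction:
    def test_identical_adjacent_loci_merge(self):
        table = random_prob_table(3, 4, seed=2, n_chroms=1)
        probs = table.probs.copy()
        probs[:, 1, :] = probs[:, 0, :]
        table = FounderProbTable(table.strain_ids, table.markers, probs)
        reduced = cp.reduce_adjacent_loci(table, threshold=0.01)
        assert reduced.n_loci == 3
        np.testing.assert_allclose(reduced.probs[:, 0, :], probs[:, 0, :], atol=1e-12)

    def test_distant_loci_untouched(self):
        # Dirichlet(0.3) rows are nearly mutually orthogonal: distances > 0.2
        table = random_prob_table(4, 10, seed=3, concentration=0.05)
        reduced = cp.reduce_adjacent_loci(table, threshold=0.10)
        assert reduced.n_loci == table.n_loci
        np.testing.assert_allclose(reduced.probs, table.probs, atol=1e-12)

    @staticmethod
    def _greedy_oracle(table, abs_thr):
        """Brute-force greedy left-to-right run merging, per chromosome."""
        runs = []
        chroms = table.markers.chromosomes
        for chrom in table.markers.chromosome_labels():
            idx = [int(i) for i in np.flatnonzero(chroms == chrom)]
            run = [idx[0]]
            for l in idx[1:]:
                avg = table.probs[:, run, :].mean(axis=1)
                dist = [np.linalg.norm(table.probs[s, l, :] - avg[s]) for s in range(table.n_strains)]
                if max(dist) < abs_thr:
                    run.append(l)
                else:
                    runs.append(run)
                    run = [l]
            runs.append(run)
        return runs

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_greedy_oracle(self, seed):
        table = random_prob_table(4, 10, seed=seed, concentration=5.0)
        expected_runs = self._greedy_oracle(table, abs_thr=0.10 * cp.MAX_L2_NORM)
        reduced, prov = cp.reduce_adjacent_loci(table, 0.10, return_provenance=True)
        assert reduced.n_loci == len(expected_runs)
        for j, run in enumerate(expected_runs):
            np.testing.assert_allclose(
                reduced.probs[:, j, :], table.probs[:, run, :].mean(axis=1), atol=1e-9
            )
            assert prov.loc[j, "n_source"] == len(run)

    @settings(deadline=None, max_examples=10)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent_on_mosaic_tables(self, seed):
        # On mosaic-like genomes (near-one-hot vectors, the intended input)
        # run distances are either tiny or near sqrt(2), so a second pass
        # with the same threshold is a no-op.
        table = cp.simulate_ri_panel(
            cp.SyntheticGenomeConfig(
                n_strains=4, chrom_lengths_mb=(20.0,), block_length_mb=5.0,
                softening=0.05, seed=seed,
            )
        )
        once = cp.reduce_adjacent_loci(table, 0.10)
        twice = cp.reduce_adjacent_loci(once, 0.10)
        assert twice.n_loci == once.n_loci
        np.testing.assert_allclose(twice.probs, once.probs, atol=1e-12)

    def test_never_merges_across_chromosomes(self):
        table = random_prob_table(3, 6, seed=5, n_chroms=2)
        probs = np.zeros_like(table.probs)
        probs[:, :, 0] = 1.0  # every locus identical -> only chromosomes separate runs
        table = FounderProbTable(table.strain_ids, table.markers, probs)
        reduced = cp.reduce_adjacent_loci(table, 0.10)
        assert reduced.n_loci == 2
        assert reduced.markers.chromosome_labels() == ["1", "2"]


class TestDosageAndCalls:
    def test_certain_and_mixed_diplotypes(self):
        table = random_prob_table(3, 2, seed=6)
        probs = np.zeros_like(table.probs)
        probs[0, :, 0] = 1.0  # certain AA
        probs[1, :, 8] = 1.0  # certain AB
        probs[2, :, 0] = 0.5  # half AA, half BB
        probs[2, :, 1] = 0.5
        table = FounderProbTable(table.strain_ids, table.markers, probs)
        dos = cp.haplotype_dosage(table, 0)
        np.testing.assert_allclose(dos[0], [2, 0, 0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(dos[1], [1, 1, 0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(dos[2], [1, 1, 0, 0, 0, 0, 0, 0])

    def test_dosage_rows_sum_to_two(self, soft_panel):
        dos = cp.haplotype_dosages(soft_panel)
        np.testing.assert_allclose(dos.sum(axis=2), 2.0, atol=1e-9)

    def test_hard_calls_argmax_tie_and_idempotence(self):
        table = random_prob_table(2, 2, seed=7)
        probs = np.zeros_like(table.probs)
        probs[0, :, 0], probs[0, :, 1] = 0.9, 0.1      # clear AA
        probs[1, :, 0], probs[1, :, 1] = 0.5, 0.5      # exact AA/BB tie -> AA
        table = FounderProbTable(table.strain_ids, table.markers, probs)
        calls = cp.hard_call_diplotypes(table)
        assert np.all(calls == 0)
        D = cp.diplotype_incidence(table, 0)
        assert D.shape == (2, 36) and np.all(D[:, 0] == 1)
        # one-hot input is a fixed point
        onehot = FounderProbTable(table.strain_ids, table.markers, D[:, None, :].repeat(2, 1))
        np.testing.assert_array_equal(cp.diplotype_incidence(onehot, 0), D)


class TestKinship:
    def test_identical_genomes_and_disjoint_founders(self):
        table = random_prob_table(3, 4, seed=8)
        probs = np.zeros_like(table.probs)
        probs[0, :, 0] = 1.0  # strain 0: all AA
        probs[1, :, 0] = 1.0  # strain 1: identical to 0
        probs[2, :, 1] = 1.0  # strain 2: all BB
        table = FounderProbTable(table.strain_ids, table.markers, probs)
        K = cp.compute_kinship(table).matrix
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 2] == pytest.approx(0.0)

    def test_matches_bruteforce_double_loop(self):
        table = random_prob_table(3, 5, seed=9)
        shares = cp.haplotype_dosages(table) / 2.0
        n, L = table.n_strains, table.n_loci
        expected = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                expected[i, j] = np.mean(
                    [shares[i, l] @ shares[j, l] for l in range(L)]
                )
        np.testing.assert_allclose(cp.compute_kinship(table).matrix, expected, atol=1e-12)

    @pytest.mark.parametrize("n,L,seed", [(2, 3, 0), (4, 7, 1), (5, 10, 2)])
    def test_bruteforce_on_small_tables(self, n, L, seed):
        table = random_prob_table(n, L, seed=seed)
        shares = cp.haplotype_dosages(table) / 2.0
        expected = np.zeros((n, n))
        for l in range(L):
            expected += shares[:, l, :] @ shares[:, l, :].T
        expected /= L
        K = cp.compute_kinship(table)
        np.testing.assert_allclose(K.matrix, expected, atol=1e-12)
        # PSD within tolerance, diagonal dominates off-diagonal
        w = np.linalg.eigvalsh(K.matrix)
        assert w.min() > -1e-10

    def test_balanced_kinship(self):
        K = cp.KinshipMatrix(
            matrix=np.array([[1.0, 0.1, 0.2], [0.1, 1.0, 0.3], [0.2, 0.3, 1.0]]),
            strain_ids=["a", "b", "c"],
        )
        B = cp.balanced_kinship(K).matrix
        off = B[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.2)
        np.testing.assert_allclose(np.diag(B), np.diag(K.matrix))
        # fixed point: balancing twice changes nothing
        np.testing.assert_allclose(cp.balanced_kinship(cp.balanced_kinship(K)).matrix, B)

    def test_pcs_for_variance_edge_cases(self):
        ident = cp.KinshipMatrix(np.eye(20), [f"s{i}" for i in range(20)])
        assert cp.pcs_for_variance(ident, 0.95) == 19
        v = np.ones(5) / np.sqrt(5)
        rank1 = cp.KinshipMatrix(np.outer(v, v), [f"s{i}" for i in range(5)])
        assert cp.pcs_for_variance(rank1, 0.95) == 1

    def test_pcs_nonincreasing_with_off_diagonal_mean(self):
        # K(rho) = (1-rho) I + rho J: structure strengthens as rho rises
        ids = [f"s{i}" for i in range(15)]
        counts = []
        for rho in [0.0, 0.2, 0.4, 0.6, 0.8]:
            K = cp.KinshipMatrix((1 - rho) * np.eye(15) + rho * np.ones((15, 15)), ids)
            counts.append(cp.pcs_for_variance(K, 0.95))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
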