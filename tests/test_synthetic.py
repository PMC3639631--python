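import numpy as np
import pytest

from fractalseq.encoding import encode_atomic
from fractalseq.entropy import di_entropy, mono_entropy
from fractalseq.fractal import higuchi_fd
from fractalseq.stats import skewness
from fractalseq.synthetic import (
    DEFAULT_GENE_SKEWS,
    UnattainableTargetError,
    fluctuation_transition,
    gen_expression_table,
    gen_fbm_series,
    gen_iid_sequence,
    gen_markov_sequence,
    gen_pair_panel,
    stationary_distribution,
)


class TestIidSequence:
    def test_fixed_seed_reproduces(self):
        a = gen_iid_sequence(500, seed=7)
        b = gen_iid_sequence(500, seed=7)
        assert a.residues == b.residues

    def test_degenerate_probabilities_give_homopolymer(self):
        seq = gen_iid_sequence(50, probs=(1, 0, 0, 0), seed=0)
        assert seq.residues == "A" * 50

    def test_uniform_draw_approaches_max_entropy(self):
        seq = gen_iid_sequence(100_000, seed=1)
        assert mono_entropy(seq) == pytest.approx(2.0, abs=0.01)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            gen_iid_sequence(10, probs=(0.5, 0.5, 0.5, 0.5))


class TestMarkovSequence:
    def test_uniform_matrix_reduces_to_iid(self):
        P = np.full((4, 4), 0.25)
        seq = gen_markov_sequence(100_000, P, seed=2)
        assert di_entropy(seq) == pytest.approx(4.0, abs=0.01)

    def test_deterministic_cycle_has_two_bit_pairs(self):
        # A->C->G->T->A: the four realized pairs are equiprobable
        P = np.zeros((4, 4))
        for i in range(4):
            P[i, (i + 1) % 4] = 1.0
        seq = gen_markov_sequence(4001, P, seed=3)  # 4000 pairs, 1000 per state
        assert di_entropy(seq) == pytest.approx(2.0, abs=1e-9)

    def test_sticky_chain_suppresses_pair_entropy(self):
        sticky = fluctuation_transition(0.9)
        uniform = fluctuation_transition(0.0)
        s_sticky = gen_markov_sequence(20_000, sticky, seed=4)
        s_unif = gen_markov_sequence(20_000, uniform, seed=4)
        assert di_entropy(s_sticky) < di_entropy(s_unif) - 0.5

    def test_empirical_pairs_match_stationary_pair_distribution(self):
        P = fluctuation_transition(0.5)
        pi = stationary_distribution(P)
        seq = gen_markov_sequence(200_000, P, seed=5)
        bases = "ACGT"
        expected = {
            a + b: pi[i] * P[i, j]
            for i, a in enumerate(bases)
            for j, b in enumerate(bases)
        }
        r = seq.residues
        n_pairs = len(r) - 1
        for state, p in expected.items():
            count = sum(
                1 for i in range(n_pairs) if r[i] == state[0] and r[i + 1] == state[1]
            )
            assert count / n_pairs == pytest.approx(p, abs=0.01)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            gen_markov_sequence(10, np.eye(4) * 0.5)


class TestFbm:
    def test_same_seed_same_path(self):
        a = gen_fbm_series(1000, 0.7, seed=9)
        b = gen_fbm_series(1000, 0.7, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_standard_brownian_increments_uncorrelated(self):
        path = gen_fbm_series(50_000, 0.5, seed=10)
        inc = np.diff(path.values)
        rho = np.corrcoef(inc[:-1], inc[1:])[0, 1]
        assert abs(rho) < 0.02

    def test_persistent_path_has_low_dimension(self):
        fds = [higuchi_fd(gen_fbm_series(10_000, 0.8, seed=s).values).fd for s in range(5)]
        assert np.mean(fds) == pytest.approx(1.2, abs=0.1)

    def test_hurst_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gen_fbm_series(100, 1.5)


@pytest.fixture(scope="module")
def panel():
    return gen_pair_panel(n_pairs=6, n_offline=1, seed=11)


class TestPairPanel:

    def test_achieved_dimensions_within_tolerance(self, panel):
        d = panel.planted
        assert (d.fd_mrna_planted - d.fd_mrna_achieved).abs().max() <= 0.003
        assert (d.fd_cds_planted - d.fd_cds_achieved).abs().max() <= 0.003

    def test_pairs_are_structurally_valid(self, panel):
        for pair in panel.pairs:
            assert pair.mrna.residues[pair.cds_start - 1 : pair.cds_end] == pair.cds.residues
            assert len(pair.noncoding) == len(pair.mrna) - len(pair.cds)

    def test_achieved_matches_recomputed_dimension(self, panel):
        row = panel.planted.iloc[0]
        pair = panel.pairs[0]
        assert higuchi_fd(encode_atomic(pair.mrna)).fd == pytest.approx(
            row.fd_mrna_achieved, abs=1e-12
        )

    def test_single_pair_panel_is_valid(self):
        panel = gen_pair_panel(n_pairs=1, n_offline=0, seed=12)
        assert len(panel.pairs) == 1

    def test_unattainable_dimension_raises(self):
        with pytest.raises(UnattainableTargetError, match="3.0"):
            gen_pair_panel(
                n_pairs=1, n_offline=0, slope=1.0, intercept=0.0,
                fd_mrna_range=(3.0, 3.0), seed=13,
            )

    def test_reproducible_under_seed(self):
        a = gen_pair_panel(n_pairs=3, n_offline=0, seed=14)
        b = gen_pair_panel(n_pairs=3, n_offline=0, seed=14)
        assert a.pairs[2].mrna.residues == b.pairs[2].mrna.residues


class TestExpressionTable:
    def test_shape_and_default_genes(self):
        t = gen_expression_table(seed=15)
        assert t.shape == (len(DEFAULT_GENE_SKEWS), 168 * 4)
        assert list(t.index) == list(DEFAULT_GENE_SKEWS)

    def test_rows_are_z_scores(self):
        t = gen_expression_table(seed=16)
        assert np.allclose(t.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(t.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_normal_gene_has_small_skew(self):
        t = gen_expression_table(genes={"flat": 0.0}, seed=17)
        assert abs(skewness(t.loc["flat"].to_numpy()).skewness) < 0.2

    def test_planted_skew_ordering_holds_across_seeds(self):
        wins = 0
        for s in range(100):
            t = gen_expression_table(genes={"tail": 2.2, "flat": 0.0}, seed=s)
            sk_tail = skewness(t.loc["tail"].to_numpy()).skewness
            sk_flat = skewness(t.loc["flat"].to_numpy()).skewness
            wins += sk_tail > sk_flat
        assert wins >= 95

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            gen_expression_table(n_regions=2)
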