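import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from paralogsel.codon import (
    AMINO_ACIDS,
    CODON_INDEX,
    N_CODONS,
    SENSE_CODONS,
    CodonLikelihood,
    CodonPartitionAlignment,
    branch_partition,
    build_mg94_generator,
    codon_frequencies_from_f3x4,
    contrast_fel_site_test,
    encode_codon,
    f3x4_frequencies,
    fel_site_test,
    fit_global_nuisance,
    stationary_distribution,
)
from paralogsel.codon import _decompose, _propagators
from paralogsel.phylo import read_newick
from paralogsel.simulate import TreeSpec, simulate_codon_alignment, simulate_tree

UNIFORM = np.full((3, 4), 0.25)


def small_aln(seqs, newick, partition=None):
    ids = list(seqs)
    tree = read_newick(newick)
    partition = partition or dict.fromkeys(ids, "alpha")
    return CodonPartitionAlignment.from_sequences(ids, list(seqs.values()), partition, tree)


class TestGenerator:
    def test_61_sense_codons(self):
        assert N_CODONS == 61
        assert "TAA" not in CODON_INDEX and "TGA" not in CODON_INDEX and "TAG" not in CODON_INDEX

    def test_multi_nucleotide_entries_zero(self):
        Q = build_mg94_generator(2.0, UNIFORM, 1.0, 0.5)
        for i, j in itertools.product(range(N_CODONS), repeat=2):
            if i == j:
                continue
            diff = sum(a != b for a, b in zip(SENSE_CODONS[i], SENSE_CODONS[j]))
            if diff > 1:
                assert Q[i, j] == 0.0

    def test_beta_zero_blocks_nonsynonymous_flux(self):
        Q = build_mg94_generator(2.0, UNIFORM, 1.0, 0.0)
        for i, j in itertools.product(range(N_CODONS), repeat=2):
            if i != j and AMINO_ACIDS[i] != AMINO_ACIDS[j]:
                assert Q[i, j] == 0.0

    def test_rows_sum_to_zero(self):
        Q = build_mg94_generator(3.0, UNIFORM, 0.7, 1.3)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_stationary_vector_annihilates(self):
        pf = np.array([[0.4, 0.2, 0.2, 0.2], [0.25, 0.25, 0.3, 0.2], [0.1, 0.3, 0.3, 0.3]])
        Q = build_mg94_generator(2.5, pf, 1.0, 0.4)
        pi = stationary_distribution(pf)
        assert np.max(np.abs(pi @ Q)) < 1e-10

    def test_time_reversibility(self):
        pf = np.array([[0.4, 0.2, 0.2, 0.2], [0.25, 0.25, 0.3, 0.2], [0.1, 0.3, 0.3, 0.3]])
        Q = build_mg94_generator(2.5, pf, 1.0, 0.4)
        pi = stationary_distribution(pf)
        flux = pi[:, None] * Q
        assert np.max(np.abs(flux - flux.T)) < 1e-12

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            build_mg94_generator(2.0, np.full((3, 4), 0.3))

    def test_propagator_matches_expm(self):
        Q = build_mg94_generator(2.0, UNIFORM, 1.0, 0.3)
        pi = stationary_distribution(UNIFORM)
        P = _propagators(_decompose(Q, pi), np.array([0.6]))[0]
        assert np.max(np.abs(P - expm(Q * 0.6))) < 1e-10
        assert np.allclose(P.sum(axis=1), 1.0)


class TestFrequencies:
    def test_uniform_composition_near_uniform_codons(self):
        # all 61 sense codons once: composition close to uniform
        idx = np.arange(N_CODONS)[None, :]
        pf = f3x4_frequencies(idx)
        pi = codon_frequencies_from_f3x4(pf)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert pi.max() / pi.min() < 2.0

    def test_gaps_ignored(self):
        idx = np.array([[CODON_INDEX["ATG"], -1, CODON_INDEX["ATG"]]])
        pf = f3x4_frequencies(idx)
        assert pf[0].argmax() == 0  # A dominates position 1


class TestEncoding:
    def test_gap_and_ambiguous(self):
        assert encode_codon("---") == -1
        assert encode_codon("ANN") == -1

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            encode_codon("TAA")

    def test_sense(self):
        assert SENSE_CODONS[encode_codon("atg")] == "ATG"


class TestPruningOracle:
    @pytest.mark.parametrize("seed", range(3))
    def test_three_tip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tree = read_newick("(A:0.3,B:0.6,C:0.2);")
        codons = rng.integers(0, N_CODONS, size=(3, 2))
        aln = CodonPartitionAlignment(
            ids=["A", "B", "C"], codons=codons,
            partition=dict.fromkeys("ABC", "alpha"), tree=tree,
        )
        Q = build_mg94_generator(2.0, UNIFORM, 1.0, 0.5)
        pi = stationary_distribution(UNIFORM)
        engine = CodonLikelihood(aln)
        lengths = engine.lengths
        P = np.array([expm(Q * t) for t in lengths])
        ll = engine.loglik(P, pi)
        # independent enumeration over the root state
        order = [tree.nodes[engine._child[e]].label for e in range(3)]
        expected = 0.0
        for s in range(aln.n_sites):
            site_lik = 0.0
            for r in range(N_CODONS):
                p = pi[r]
                for e, label in enumerate(order):
                    tip_codon = codons[["A", "B", "C"].index(label), s]
                    p *= P[e][r, tip_codon]
                site_lik += p
            expected += np.log(site_lik)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_gap_codon_is_fully_ambiguous(self):
        tree = read_newick("(A:0.3,B:0.6,C:0.2);")
        aln = CodonPartitionAlignment(
            ids=["A", "B", "C"],
            codons=np.array([[0], [5], [-1]]),
            partition=dict.fromkeys("ABC", "alpha"), tree=tree,
        )
        Q = build_mg94_generator(2.0, UNIFORM, 1.0, 0.5)
        pi = stationary_distribution(UNIFORM)
        engine = CodonLikelihood(aln)
        P = np.array([expm(Q * t) for t in engine.lengths])
        ll_gap = engine.loglik(P, pi)
        # marginalizing C by hand: sum over its states = 1, equal to 2-tip likelihood
        total = 0.0
        order = [tree.nodes[engine._child[e]].label for e in range(3)]
        for r in range(N_CODONS):
            p = pi[r]
            for e, label in enumerate(order):
                if label == "A":
                    p *= P[e][r, 0]
                elif label == "B":
                    p *= P[e][r, 5]
            total += p
        assert ll_gap == pytest.approx(np.log(total), abs=1e-10)


@pytest.fixture(scope="module")
def fitted_alignment():
    tree = simulate_tree(TreeSpec(40, delta_fraction=0.4, scale=0.2), seed=11)
    partition = {
        n.label: ("delta" if n.branch_class == "delta" else "alpha")
        for n in tree.nodes if n.is_tip
    }
    aln = simulate_codon_alignment(tree, partition, [(0.4, 0.4)] * 60, kappa=2.5, seed=12)
    nuisance = fit_global_nuisance(aln)
    return aln, nuisance


class TestNuisanceFit:
    def test_kappa_recovery(self, fitted_alignment):
        _, nuisance = fitted_alignment
        assert 1.5 < nuisance.kappa < 4.5

    def test_duplicating_sequences_keeps_kappa(self, fitted_alignment):
        aln, nuisance = fitted_alignment
        tree2 = aln.tree.copy()
        # graft a zero-length duplicate of every tip: likelihood doubles per site
        # (cheaper equivalent check: duplicated alignment rows via doubled sites)
        doubled = CodonPartitionAlignment(
            ids=aln.ids, codons=np.hstack([aln.codons, aln.codons]),
            partition=aln.partition, tree=tree2,
        )
        nu2 = fit_global_nuisance(doubled)
        assert nu2.kappa == pytest.approx(nuisance.kappa, rel=0.05)

    def test_no_signal_error(self):
        seqs = dict.fromkeys(["A", "B", "C"], "ATGATG")
        aln = small_aln(seqs, "(A:0.1,B:0.1,C:0.1);")
        with pytest.raises(ValueError, match="signal|identical"):
            fit_global_nuisance(aln)

    def test_too_few_sequences(self):
        seqs = {"A": "ATG", "B": "CTG"}
        tree = read_newick("(A:0.1,B:0.1);")
        aln = CodonPartitionAlignment.from_sequences(
            list(seqs), list(seqs.values()), dict.fromkeys(seqs, "alpha"), tree
        )
        with pytest.raises(ValueError):
            fit_global_nuisance(aln)


class TestFelSiteTest:
    def test_invariant_site_flagged(self, fitted_alignment):
        aln, nuisance = fitted_alignment
        codons = aln.codons.copy()
        codons[:, 0] = CODON_INDEX["ATG"]
        forced = CodonPartitionAlignment(
            ids=aln.ids, codons=codons, partition=aln.partition, tree=aln.tree
        )
        res = fel_site_test(forced, 0, "alpha", nuisance)
        assert res.untestable and res.p_value == 1.0
        assert res.alpha == 0.0 and res.beta["tested"] == 0.0

    def test_determinism(self, fitted_alignment):
        aln, nuisance = fitted_alignment
        a = fel_site_test(aln, 0, "alpha", nuisance)
        b = fel_site_test(aln, 0, "alpha", nuisance)
        assert a.p_value == b.p_value and a.dnds == b.dnds

    def test_synonymous_only_site_gives_zero_dnds(self):
        # two codons for Leu (CTT/CTC) varying: dN/dS should hit 0
        tree = simulate_tree(TreeSpec(12, scale=0.3), seed=3)
        ids = tree.tip_labels
        rng = np.random.default_rng(0)
        syn = [CODON_INDEX["CTT"], CODON_INDEX["CTC"]]
        codons = rng.integers(0, N_CODONS, size=(12, 30))
        codons[:, 0] = rng.choice(syn, size=12)
        aln = CodonPartitionAlignment(
            ids=ids, codons=codons, partition=dict.fromkeys(ids, "alpha"), tree=tree
        )
        nuisance = fit_global_nuisance(aln)
        res = fel_site_test(aln, 0, "alpha", nuisance)
        assert res.beta["tested"] == pytest.approx(0.0, abs=1e-5)
        assert res.dnds["tested"] == pytest.approx(0.0, abs=1e-4)
        assert res.direction == "dN<dS"

    def test_empty_branch_set_rejected(self, fitted_alignment):
        aln, nuisance = fitted_alignment
        with pytest.raises(ValueError):
            fel_site_test(aln, 0, np.zeros(len(aln.tree.nodes) - 1, dtype=bool), nuisance)


class TestContrastFel:
    def test_cloned_partition_null(self):
        # delta partition is a mirror of alpha: estimates equal, p = 1
        tree = read_newick("((A1:0.1,A2:0.1):0.05,(D1:0.1,D2:0.1):0.05);")
        seqs = {"A1": "ATGCTT", "A2": "ATACTC", "D1": "ATGCTT", "D2": "ATACTC"}
        partition = {"A1": "alpha", "A2": "alpha", "D1": "delta", "D2": "delta"}
        aln = small_aln(seqs, tree.write_newick(), partition)
        nuisance = fit_global_nuisance(aln)
        res = contrast_fel_site_test(aln, 0, nuisance)
        assert res.statistic == pytest.approx(0.0, abs=1e-4)
        assert res.p_value == pytest.approx(1.0, abs=1e-3)

    def test_label_swap_inverts_ratio(self):
        # sister-clade partition: every branch is pure, so the swap is exact
        left = simulate_tree(TreeSpec(10, scale=0.25), seed=21).write_newick()[:-1]
        right = simulate_tree(TreeSpec(10, scale=0.25), seed=22).write_newick()[:-1]
        left = left.replace("t", "a")
        right = right.replace("t", "d")
        tree = read_newick(f"({left}:0.05,{right}:0.05);")
        partition = {l: ("alpha" if l.startswith("a") else "delta") for l in tree.tip_labels}
        aln = simulate_codon_alignment(tree, partition, [(0.1, 1.0)] + [(0.4, 0.4)] * 40, seed=23)
        nuisance = fit_global_nuisance(aln)
        res = contrast_fel_site_test(aln, 0, nuisance)
        swapped = CodonPartitionAlignment(
            ids=aln.ids, codons=aln.codons,
            partition={k: ("alpha" if v == "delta" else "delta") for k, v in aln.partition.items()},
            tree=aln.tree,
        )
        res_s = contrast_fel_site_test(swapped, 0, nuisance)
        assert res_s.p_value == pytest.approx(res.p_value, abs=1e-3)
        if res.dnds["ratio"] > 0 and np.isfinite(res.dnds["ratio"]):
            assert res_s.dnds["ratio"] == pytest.approx(1.0 / res.dnds["ratio"], rel=0.05)

    def test_single_partition_rejected(self):
        seqs = {"A": "ATG", "B": "CTG", "C": "TTG"}
        aln = small_aln(seqs, "(A:0.1,B:0.1,C:0.1);")
        nuisance_stub = None
        with pytest.raises(ValueError):
            contrast_fel_site_test(aln, 0, nuisance_stub)


class TestBranchPartition:
    def test_pure_delta_clade(self):
        tree = read_newick("((D1:1,D2:1):1,(A1:1,A2:1):1);")
        partition = {"D1": "delta", "D2": "delta", "A1": "alpha", "A2": "alpha"}
        mask = branch_partition(tree, partition)
        assert mask.sum() == 3  # two delta tips + their stem


class TestAlignmentValidation:
    def test_tree_mismatch(self):
        tree = read_newick("(A:1,B:1,X:1);")
        with pytest.raises(ValueError, match="match"):
            CodonPartitionAlignment.from_sequences(
                ["A", "B", "C"], ["ATG"] * 3, dict.fromkeys("ABC", "alpha"), tree
            )

    def test_bad_partition_label(self):
        tree = read_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError):
            CodonPartitionAlignment.from_sequences(
                ["A", "B", "C"], ["ATG"] * 3, dict.fromkeys("ABC", "gamma"), tree
            )

    def test_stop_codon_rejected(self):
        tree = read_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="stop"):
            CodonPartitionAlignment.from_sequences(
                ["A", "B", "C"], ["TAA", "ATG", "ATG"], dict.fromkeys("ABC", "alpha"), tree
            )
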