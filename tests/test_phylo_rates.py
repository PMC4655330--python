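"""Likelihood core, branch-length fitting, clade rates and the bootstrap test."""

import math

import numpy as np
import pytest

from plastevo._likelihood import (
    ReversibleModel,
    discrete_gamma_rates,
    gtr_rate_matrix,
)
from plastevo.alignment import Alignment
from plastevo.indel_coding import simple_indel_coding
from plastevo.phylo_rates import (
    CalibratedClade,
    SubstitutionModel,
    bootstrap_rate_test,
    clade_mean_rate,
    fit_branch_lengths,
    loglikelihood,
)
from plastevo.trees import PhyloTree

JC = SubstitutionModel(kind="GTR+G", exchangeabilities=np.ones(6), freqs=np.ones(4) / 4,
                       alpha=1.0, n_categories=1)


def test_single_site_zero_branches_gives_log_pi():
    tree = PhyloTree.from_newick("(a:0,b:0);")
    aln = Alignment(taxa=["a", "b"], rows=["G", "G"])
    assert loglikelihood(aln, tree, JC) == pytest.approx(math.log(0.25), abs=1e-6)


@pytest.mark.parametrize("t", [0.05, 0.3, 1.2])
def test_jukes_cantor_closed_form(t):
    tree = PhyloTree.from_newick(f"(a:{t / 2},b:{t / 2});")
    p_match = 0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3))
    p_diff = 0.25 * (0.25 - 0.25 * math.exp(-4 * t / 3))
    aln_m = Alignment(taxa=["a", "b"], rows=["A", "A"])
    aln_d = Alignment(taxa=["a", "b"], rows=["A", "C"])
    assert loglikelihood(aln_m, tree, JC) == pytest.approx(math.log(p_match), abs=1e-10)
    assert loglikelihood(aln_d, tree, JC) == pytest.approx(math.log(p_diff), abs=1e-10)


def _enumeration_loglik(aln, tree, exch, freqs, alpha, ncat):
    """Sum over all internal-state assignments on the fixed 4-taxon topology."""
    rev = ReversibleModel(gtr_rate_matrix(exch, freqs), freqs)
    rates = discrete_gamma_rates(alpha, ncat)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    root = tree.root
    chl, chr_ = root.children
    total = 0.0
    for site in range(aln.n_cols):
        obs = [code[aln.row(t)[site]] for t in ("a", "b", "c", "d")]
        site_lik = 0.0
        for r in rates:
            P = {n: rev.transition_matrix(r * n.length) for n in tree.postorder if n.parent}
            s = 0.0
            for x in range(4):
                for y in range(4):
                    for z in range(4):
                        s += (
                            freqs[x]
                            * P[chl][x, y] * P[chr_][x, z]
                            * P[chl.children[0]][y, obs[0]] * P[chl.children[1]][y, obs[1]]
                            * P[chr_.children[0]][z, obs[2]] * P[chr_.children[1]][z, obs[3]]
                        )
            site_lik += s / len(rates)
        total += math.log(site_lik)
    return total


def test_pruning_equals_enumeration_oracle():
    rng = np.random.default_rng(0)
    tree = PhyloTree.from_newick("((a:0.1,b:0.23):0.07,(c:0.31,d:0.05):0.12);")
    rows = ["".join(rng.choice(list("ACGT"), size=25)) for _ in range(4)]
    aln = Alignment(taxa=list("abcd"), rows=rows)
    exch = np.array([1.3, 3.2, 0.7, 1.1, 4.0, 1.0])
    freqs = np.array([0.31, 0.19, 0.22, 0.28])
    model = SubstitutionModel(kind="GTR+G", exchangeabilities=exch, freqs=freqs, alpha=0.7)
    assert loglikelihood(aln, tree, model) == pytest.approx(
        _enumeration_loglik(aln, tree, exch, freqs, 0.7, 4), abs=1e-10
    )


def test_loglik_invariant_under_taxon_reordering():
    rng = np.random.default_rng(1)
    tree = PhyloTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.08):0.1);")
    rows = ["".join(rng.choice(list("ACGTN-"), size=40)) for _ in range(4)]
    aln1 = Alignment(taxa=list("abcd"), rows=rows)
    aln2 = Alignment(taxa=list("dcba"), rows=rows[::-1])
    model = SubstitutionModel(kind="GTR+G", exchangeabilities=np.ones(6),
                              freqs=np.array([0.3, 0.2, 0.2, 0.3]), alpha=0.5)
    assert loglikelihood(aln1, tree, model) == pytest.approx(
        loglikelihood(aln2, tree, model), abs=1e-9
    )


def test_invalid_inputs_rejected():
    tree = PhyloTree.from_newick("(a:0.1,b:0.1);")
    with pytest.raises(ValueError):
        loglikelihood(Alignment(taxa=["a", "b"], rows=["", ""]), tree, JC)
    bad = SubstitutionModel(kind="GTR+G", exchangeabilities=np.ones(6), freqs=np.ones(4) / 4,
                            alpha=-1.0)
    with pytest.raises(ValueError):
        loglikelihood(Alignment(taxa=["a", "b"], rows=["A", "A"]), tree, bad)


def test_fit_identical_sequences_hits_lower_bound():
    tree = PhyloTree.from_newick("((a:0.1,b:0.1):0.1,c:0.1);")
    aln = Alignment(taxa=["a", "b", "c"], rows=["ACGT" * 10] * 3)
    fitted, model, _ = fit_branch_lengths(aln, tree, "GTR+G")
    assert all(n.length < 1e-6 for n in fitted.branch_nodes())


def test_clade_mean_rate_hand_arithmetic():
    # 3-tip tree; crown of (a,b) at depth paths {0.02, 0.03}, age 50 Ma
    tree = PhyloTree.from_newick("((a:0.02,b:0.03):0.01,c:0.05);")
    clade = CalibratedClade(name="ab", taxa=("a", "b"), age_ma=50.0)
    assert clade_mean_rate(tree, clade) == pytest.approx(5.0e-4)


def test_clade_mean_rate_clock_identity():
    r, age = 2e-3, 10.0
    tree = PhyloTree.from_newick(f"((a:{r * age / 2},b:{r * age / 2}):{r * age / 2},"
                                 f"(c:{r * age * 0.75},d:{r * age * 0.75}):{r * age / 4});")
    clade = CalibratedClade(name="all", taxa=("a", "b", "c", "d"), age_ma=age)
    assert clade_mean_rate(tree, clade) == pytest.approx(r)


def test_clade_rate_scales_linearly_with_branch_lengths():
    tree = PhyloTree.from_newick("((a:0.02,b:0.03):0.01,c:0.05);")
    clade = CalibratedClade(name="ab", taxa=("a", "b"), age_ma=50.0)
    base = clade_mean_rate(tree, clade)
    for node in tree.branch_nodes():
        node.length *= 3.0
    assert clade_mean_rate(tree, clade) == pytest.approx(3.0 * base)


def test_non_monophyletic_clade_raises():
    tree = PhyloTree.from_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
    with pytest.raises(ValueError, match="monophyletic"):
        clade_mean_rate(tree, CalibratedClade(name="bad", taxa=("a", "c"), age_ma=10.0))


def test_binary_model_fits_indel_matrix():
    rows = ["AC--TTAGGA", "ACGGTTA--A", "AC--TTA--A", "ACGGTTAGGA"]
    aln = Alignment(taxa=list("abcd"), rows=rows, gene="g")
    matrix = simple_indel_coding(aln)
    tree = PhyloTree.from_newick("((a:0.1,c:0.1):0.05,(b:0.1,d:0.1):0.05);")
    fitted, model, logl = fit_branch_lengths(matrix, tree, "BIN+G")
    assert model.kind == "BIN+G"
    assert logl < 0
    assert all(np.isfinite(n.length) for n in fitted.branch_nodes())


def test_bootstrap_deterministic_under_same_seed():
    rng = np.random.default_rng(5)
    tree = PhyloTree.from_newick("((a:0.02,b:0.03):0.01,(c:0.04,d:0.02):0.015);")
    from plastevo.synthetic_data import evolve_alignment

    aln, _ = evolve_alignment(tree, 800, seed=4, alpha=None)
    clade = CalibratedClade(name="ab", taxa=("a", "b"), age_ma=10.0)
    r1 = bootstrap_rate_test(aln, tree, "GTR+G", [clade], n=5, seed=99)["ab"]
    r2 = bootstrap_rate_test(aln, tree, "GTR+G", [clade], n=5, seed=99)["ab"]
    assert r1.bootstrap_mean == r2.bootstrap_mean
    assert r1.p == r2.p
    assert np.array_equal(r1.bootstrap_rates, r2.bootstrap_rates)


def test_bootstrap_constant_matrix_degenerate_p_is_one():
    tree = PhyloTree.from_newick("((a:0.01,b:0.01):0.01,c:0.01);")
    aln = Alignment(taxa=["a", "b", "c"], rows=["AAAA" * 5] * 3)
    clade = CalibratedClade(name="ab", taxa=("a", "b"), age_ma=10.0)
    report = bootstrap_rate_test(aln, tree, "GTR+G", [clade], n=3, seed=1)["ab"]
    assert report.p == 1.0
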