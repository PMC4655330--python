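"""dN/dS estimation: Nei–Gojobori counting and ML codon-model fitting.

Two routes to ω = dN/dS on protein-coding alignments (plastid/bacterial
genetic code, translation table 11):

* :func:`ng86_pairwise` — the Nei–Gojobori (1986) counting estimator with
  Jukes–Cantor correction. Fast, closed-form, and fully independent of the
  likelihood machinery, which makes it the natural cross-check.
* :func:`fit_codon_model` — a Goldman–Yang-style 61-state codon model with
  F3×4 equilibrium frequencies, transition/transversion ratio κ and either a
  single global ω (``one_ratio``) or one ω per branch (``free_ratio``).
  Per-branch dN and dS follow the codeml convention: expected synonymous /
  nonsynonymous substitutions per synonymous / nonsynonymous site, with site
  counts taken from the mutational (ω = 1) version of the fitted matrix.

ω is reported as missing (NaN) wherever dS = 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy.optimize import minimize_scalar

from ._likelihood import (
    MIN_BRANCH_LENGTH,
    LikelihoodEngine,
    ReversibleModel,
    compress_patterns,
)
from .alignment import Alignment
from .trees import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "CodonAlignment",
    "OmegaReport",
    "GENETIC_CODE_ID",
    "SENSE_CODONS",
    "ng86_pairwise",
    "fit_codon_model",
]

GENETIC_CODE_ID = 11
_TABLE = unambiguous_dna_by_id[GENETIC_CODE_ID]
_BASES = "TCAG"
ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
STOP_CODONS = set(_TABLE.stop_codons)
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class CodonAlignment:
    """In-frame codon rows; gaps in whole-codon units, no internal stops."""

    taxa: list[str]
    rows: list[str]
    gene: str = ""
    code_id: int = GENETIC_CODE_ID

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows mismatch")
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) % 3:
                raise ValueError(f"{taxon}: length not divisible by 3")
            for i in range(0, len(row) - 3, 3):  # internal codons only
                if row[i : i + 3] in STOP_CODONS:
                    raise ValueError(f"{taxon}: internal stop codon at {i}")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def codons(self, taxon: str) -> list[str]:
        row = self.rows[self.taxa.index(taxon)]
        return [row[i : i + 3] for i in range(0, len(row), 3)]

    @classmethod
    def from_alignment(cls, aln: Alignment) -> "CodonAlignment":
        return cls(taxa=list(aln.taxa), rows=list(aln.rows), gene=aln.gene)


@dataclass
class OmegaReport:
    """Per-branch dN/dS decomposition of a fitted codon model."""

    mode: str
    logL: float
    kappa: float
    global_omega: float | None
    branches: dict = field(default_factory=dict)  # branch key -> dict(t, omega, dN, dS)
    tree: PhyloTree | None = None
    dn_tree: PhyloTree | None = None
    ds_tree: PhyloTree | None = None


# ---------------------------------------------------------------------------
# NG86 counting estimator


def _synonymous_fraction(codon: str) -> float:
    """Number of synonymous sites in one codon (0..3), NG86 convention."""
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if AA_OF[mutant] == AA_OF[codon]:
                syn += 1
        total += syn / 3.0
    return total


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over mutation orderings."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn = nsyn = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        path_syn = path_nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AA_OF[cur] == AA_OF[nxt]:
                path_syn += 1
            else:
                path_nsyn += 1
            cur = nxt
        if ok:
            syn += path_syn
            nsyn += path_nsyn
            n_paths += 1
    if n_paths == 0:  # every path crosses a stop; fall back to all orderings
        for order in itertools.permutations(diff_pos):
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS or AA_OF.get(cur) is None:
                    nsyn += 1
                elif AA_OF[cur] == AA_OF.get(nxt, ""):
                    syn += 1
                else:
                    nsyn += 1
                cur = nxt
            n_paths += 1
    return syn / n_paths, nsyn / n_paths


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(a: str, b: str, code_id: int = GENETIC_CODE_ID) -> tuple[float, float, float]:
    """Nei–Gojobori (dN, dS, ω) for two equal-length in-frame sequences.

    Codons containing gaps or N in either sequence are skipped pairwise.
    ω is NaN when dS is 0 or a proportion exceeds the Jukes–Cantor domain.
    """
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("sequences must be equal-length and in frame")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        c1, c2 = a[i : i + 3], b[i : i + 3]
        if set(c1 + c2) - set("ACGT"):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        S += (_synonymous_fraction(c1) + _synonymous_fraction(c2)) / 2.0
        sd, nd = _codon_differences(c1, c2)
        Sd += sd
        Nd += nd
        N += 3.0 - (_synonymous_fraction(c1) + _synonymous_fraction(c2)) / 2.0
    if S == 0 or N == 0:
        return math.nan, math.nan, math.nan
    pS, pN = Sd / S, Nd / N
    dS, dN = _jc_correct(pS), _jc_correct(pN)
    if math.isnan(dN) or math.isnan(dS) or dS == 0.0:
        omega = math.nan
    else:
        omega = dN / dS
    return dN, dS, omega


# ---------------------------------------------------------------------------
# GY94 / F3x4 machinery


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F3×4 codon frequencies: product of position-specific base frequencies,
    stop codons removed and the rest renormalized."""
    counts = np.zeros((3, 4))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for row in aln.rows:
        for i in range(0, len(row), 3):
            codon = row[i : i + 3]
            for pos, ch in enumerate(codon):
                if ch in base_idx:
                    counts[pos, base_idx[ch]] += 1
    counts += 0.5  # avoid zero classes on tiny alignments
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freqs[0, base_idx[c[0]]] * pos_freqs[1, base_idx[c[1]]] * pos_freqs[2, base_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def _single_nt_change(c1: str, c2: str) -> tuple[int, str, str] | None:
    diff = [(i, c1[i], c2[i]) for i in range(3) if c1[i] != c2[i]]
    return diff[0] if len(diff) == 1 else None


# precomputed sparse structure of single-nucleotide codon neighbours
_NEIGHBOURS: list[tuple[int, int, bool, bool]] = []  # (i, j, is_transition, is_nonsyn)
for _i, _c1 in enumerate(SENSE_CODONS):
    for _j, _c2 in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        change = _single_nt_change(_c1, _c2)
        if change is None:
            continue
        _, x, y = change
        _NEIGHBOURS.append(((_i, _j, (x, y) in _TRANSITIONS, AA_OF[_c1] != AA_OF[_c2])))


def codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray, normalize: bool = True) -> np.ndarray:
    """GY94 rate matrix: qᵢⱼ = πⱼ · κ^[transition] · ω^[nonsynonymous]."""
    Q = np.zeros((61, 61))
    for i, j, is_ts, is_nonsyn in _NEIGHBOURS:
        rate = pi[j]
        if is_ts:
            rate *= kappa
        if is_nonsyn:
            rate *= omega
        Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mu = -np.sum(pi * np.diag(Q))
        Q /= mu
    return Q


def _substitution_fractions(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """Fractions of substitutions that are synonymous / nonsynonymous."""
    syn = nonsyn = 0.0
    for i, j, is_ts, is_nonsyn in _NEIGHBOURS:
        rate = pi[i] * pi[j] * (kappa if is_ts else 1.0)
        if is_nonsyn:
            nonsyn += rate * omega
        else:
            syn += rate
    total = syn + nonsyn
    return syn / total, nonsyn / total


def _encode_codons(aln: CodonAlignment) -> tuple[np.ndarray, list[str]]:
    codes = np.full((len(aln.taxa), aln.n_codons), 61, dtype=np.int16)
    for t, row in enumerate(aln.rows):
        for s in range(aln.n_codons):
            codes[t, s] = _CODON_INDEX.get(row[3 * s : 3 * s + 3], 61)
    return codes, list(aln.taxa)


class _CodonModelCache:
    """Eigendecomposition cache keyed on (κ, ω)."""

    def __init__(self, pi: np.ndarray):
        self.pi = pi
        self._cache: dict[tuple[float, float], ReversibleModel] = {}

    def get(self, kappa: float, omega: float) -> ReversibleModel:
        key = (round(kappa, 10), round(omega, 10))
        if key not in self._cache:
            if len(self._cache) > 512:
                self._cache.clear()
            Q = codon_rate_matrix(kappa, omega, self.pi)
            self._cache[key] = ReversibleModel(Q, self.pi, normalize=False)
        return self._cache[key]


def _branch_key(node, tree: PhyloTree) -> str:
    """Stable branch label: the sorted leaf set under the branch's child node."""
    names = tree.leaf_names_under(node)
    return node.name if node.is_leaf else "|".join(sorted(names))


def fit_codon_model(
    aln: CodonAlignment,
    topology: PhyloTree,
    mode: str = "free_ratio",
    n_restarts: int = 1,
    seed: int = 0,
) -> OmegaReport:
    """ML fit of the GY94/F3×4 codon model on a fixed topology.

    ``one_ratio`` shares a single ω across the tree; ``free_ratio`` gives each
    branch its own ω (the two terminal-vs-internal contrasts of accelerated
    genes need per-branch estimates). Branches with no variation report ω as
    missing. Deterministic given inputs; optional random restarts perturb the
    starting branch lengths.
    """
    if mode not in ("one_ratio", "free_ratio"):
        raise ValueError("mode must be one_ratio or free_ratio")
    if mode == "free_ratio" and len(aln.taxa) < 3:
        raise ValueError("free_ratio requires at least 3 taxa")
    pi = f3x4_frequencies(aln)
    cache = _CodonModelCache(pi)
    codes, taxa = _encode_codons(aln)
    patterns, weights = compress_patterns(codes)
    rng = np.random.default_rng(seed)

    best = None
    for restart in range(max(1, n_restarts)):
        tree = topology.copy()
        for node in tree.branch_nodes():
            base = node.length if node.length > 0 else 0.05
            node.length = base if restart == 0 else float(base * rng.uniform(0.3, 3.0))
        engine = LikelihoodEngine(tree, patterns, weights, 61, taxa)
        kappa, omega = 2.0, 0.4
        omegas = {n.index: omega for n in tree.branch_nodes()}
        engine.set_model(cache.get(kappa, omega), np.ones(1))

        logl = engine.log_likelihood()
        for sweep in range(8):
            last = logl
            # kappa
            def neg_kappa(log_k):
                k = float(np.exp(log_k))
                _apply_models(engine, tree, cache, k, omega, omegas, mode)
                return -engine.log_likelihood()

            res = minimize_scalar(neg_kappa, bounds=(math.log(0.1), math.log(20)), method="bounded",
                                  options={"xatol": 1e-4})
            kappa = float(np.exp(res.x))
            # omega(s)
            if mode == "one_ratio":
                def neg_omega(log_w):
                    w = float(np.exp(log_w))
                    _apply_models(engine, tree, cache, kappa, w, omegas, "one_ratio")
                    return -engine.log_likelihood()

                res = minimize_scalar(neg_omega, bounds=(math.log(1e-4), math.log(20)), method="bounded",
                                      options={"xatol": 1e-4})
                omega = float(np.exp(res.x))
                _apply_models(engine, tree, cache, kappa, omega, omegas, mode)
            else:
                for node in tree.branch_nodes():
                    _apply_models(engine, tree, cache, kappa, omega, omegas, mode)
                    f = engine.branch_loglik_fn(node)  # messages exclude this branch

                    def neg_w(log_w, node=node, f=f):
                        return -f(node.length, cache.get(kappa, float(np.exp(log_w))))

                    res = minimize_scalar(neg_w, bounds=(math.log(1e-4), math.log(30)), method="bounded",
                                          options={"xatol": 1e-3})
                    omegas[node.index] = float(np.exp(res.x))
                _apply_models(engine, tree, cache, kappa, omega, omegas, mode)
            logl = engine.optimize_branch_lengths(sweeps_min=1, sweeps_max=3, tol=1e-5, xatol=1e-6)
            if logl - last < 1e-4:
                break
        if best is None or logl > best[0]:
            best = (logl, tree, kappa, omega, dict(omegas))

    logl, tree, kappa, omega, omegas = best
    report = OmegaReport(
        mode=mode,
        logL=logl,
        kappa=kappa,
        global_omega=omega if mode == "one_ratio" else None,
        tree=tree,
    )
    dn_tree, ds_tree = tree.copy(), tree.copy()
    for node, dn_node, ds_node in zip(tree.branch_nodes(), dn_tree.branch_nodes(), ds_tree.branch_nodes()):
        w = omega if mode == "one_ratio" else omegas[node.index]
        t = node.length
        frac_s, frac_n = _substitution_fractions(kappa, w, pi)
        frac_s1, frac_n1 = _substitution_fractions(kappa, 1.0, pi)
        S_sites, N_sites = 3.0 * frac_s1, 3.0 * frac_n1  # mutational opportunity per codon
        dN = t * frac_n / N_sites
        dS = t * frac_s / S_sites
        near_zero = t <= 1e-5  # no resolvable substitutions on this branch
        w_out = math.nan if (dS == 0.0 or near_zero) else dN / dS
        key = _branch_key(node, tree)
        report.branches[key] = {
            "t": t,
            "omega": w_out,
            "omega_fitted": w,
            "dN": dN,
            "dS": dS,
        }
        dn_node.length = dN
        ds_node.length = dS
    report.dn_tree, report.ds_tree = dn_tree, ds_tree
    return report


def _apply_models(engine, tree, cache, kappa, omega, omegas, mode) -> None:
    if mode == "one_ratio":
        engine.set_model(cache.get(kappa, omega), np.ones(1))
        engine.branch_models = {}
    else:
        engine.set_model(cache.get(kappa, 1.0), np.ones(1))  # root fallback (unused on edges)
        engine.branch_models = {
            n.index: cache.get(kappa, omegas[n.index]) for n in tree.branch_nodes()
        }
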