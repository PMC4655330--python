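"""Fixed-topology branch lengths, clade rates and the bootstrap rate test.

Substitution branch lengths are estimated under GTR+Γ (4 discrete
categories, empirical base frequencies, ML exchangeabilities and shape);
indel matrices use a two-state reversible model with Γ rates (BIN+Γ).
Clade mean rates divide the mean crown-to-tip path length by a fixed
calibration age in Ma, giving substitutions/site/Ma. The bootstrap test
resamples alignment columns with replacement, refits branch lengths per
replicate, and compares the bootstrap rate sample against the original
estimate with a two-sided one-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._likelihood import (
    MIN_BRANCH_LENGTH,
    LikelihoodEngine,
    ReversibleModel,
    binary_rate_matrix,
    compress_patterns,
    discrete_gamma_rates,
    gtr_rate_matrix,
)
from .alignment import Alignment
from .indel_coding import IndelCharacterMatrix
from .trees import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "SubstitutionModel",
    "CalibratedClade",
    "RateReport",
    "encode_matrix",
    "loglikelihood",
    "fit_branch_lengths",
    "clade_mean_rate",
    "bootstrap_rate_test",
]

_DNA_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BIN_CODE = {"0": 0, "1": 1}


@dataclass
class SubstitutionModel:
    """Fitted model description: GTR+Γ or BIN+Γ."""

    kind: str  # "GTR+G" | "BIN+G"
    exchangeabilities: np.ndarray | None
    freqs: np.ndarray
    alpha: float
    n_categories: int = 4

    def build(self) -> tuple[ReversibleModel, np.ndarray]:
        if self.kind.startswith("GTR"):
            Q = gtr_rate_matrix(self.exchangeabilities, self.freqs)
        elif self.kind.startswith("BIN"):
            Q = binary_rate_matrix(self.freqs)
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        rates = (
            discrete_gamma_rates(self.alpha, self.n_categories)
            if self.kind.endswith("+G")
            else np.ones(1)
        )
        return ReversibleModel(Q, self.freqs), rates


@dataclass(frozen=True)
class CalibratedClade:
    """A named clade defined by a taxon set, with a crown age in Ma."""

    name: str
    taxa: tuple
    age_ma: float

    def __post_init__(self):
        if self.age_ma <= 0:
            raise ValueError("calibration age must be positive")


@dataclass
class RateReport:
    """Clade mean rate with its bootstrap distribution and t-test."""

    clade: str
    mean_rate: float  # subst./site/Ma, original matrix
    sd: float  # across-tip spread of the original clade rates
    bootstrap_mean: float
    bootstrap_sd: float
    t: float
    p: float
    n_boot: int
    bootstrap_rates: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


# ---------------------------------------------------------------------------
# encoding


def encode_matrix(matrix: Alignment | IndelCharacterMatrix) -> tuple[np.ndarray, list[str], int]:
    """Encode rows to integer codes; returns (codes, taxa, n_states).

    Gaps, N and '?' become the missing code (``n_states``); in the
    substitution analysis gaps are missing data by contract.
    """
    if isinstance(matrix, Alignment):
        table, n_states = _DNA_CODE, 4
        taxa, rows = matrix.taxa, matrix.rows
    else:
        table, n_states = _BIN_CODE, 2
        taxa, rows = matrix.taxa, matrix.states
    if not rows or not rows[0]:
        raise ValueError("zero-length matrix")
    codes = np.full((len(rows), len(rows[0])), n_states, dtype=np.int16)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row):
            codes[i, j] = table.get(ch, n_states)
    return codes, list(taxa), n_states


def _empirical_freqs(codes: np.ndarray, n_states: int) -> np.ndarray:
    counts = np.bincount(codes[codes < n_states].ravel(), minlength=n_states).astype(float)
    counts += 1.0  # Laplace smoothing guards all-constant matrices
    return counts / counts.sum()


def _make_engine(matrix, tree: PhyloTree) -> tuple[LikelihoodEngine, np.ndarray, int]:
    codes, taxa, n_states = encode_matrix(matrix)
    if set(tree.taxa) != set(taxa):
        raise ValueError("tree taxa do not match matrix taxa")
    patterns, weights = compress_patterns(codes)
    engine = LikelihoodEngine(tree, patterns, weights, n_states, taxa)
    return engine, codes, n_states


# ---------------------------------------------------------------------------
# likelihood and fitting


def loglikelihood(matrix, tree: PhyloTree, model: SubstitutionModel) -> float:
    """Exact pruning log-likelihood of ``matrix`` on ``tree`` under ``model``."""
    engine, _, _ = _make_engine(matrix, tree)
    rev, rates = model.build()
    engine.set_model(rev, rates)
    return engine.log_likelihood()


def _fit_model_params(engine: LikelihoodEngine, model: SubstitutionModel) -> float:
    """ML-fit alpha (and GTR exchangeabilities) by bounded quasi-Newton."""
    gamma = model.kind.endswith("+G")

    if model.kind.startswith("GTR"):
        x0 = np.log(np.concatenate([model.exchangeabilities[:5], [model.alpha] if gamma else []]))

        def objective(x):
            s = np.exp(np.clip(x, -10, 10))
            model.exchangeabilities = np.concatenate([s[:5], [1.0]])
            if gamma:
                model.alpha = float(s[5])
            rev, rates = model.build()
            engine.set_model(rev, rates)
            return -engine.log_likelihood()

    elif gamma:
        x0 = np.log([model.alpha])

        def objective(x):
            model.alpha = float(np.exp(np.clip(x[0], -5, 5)))
            rev, rates = model.build()
            engine.set_model(rev, rates)
            return -engine.log_likelihood()

    else:  # BIN without gamma: frequencies empirical, nothing left to fit
        return engine.log_likelihood()

    res = optimize.minimize(objective, x0, method="L-BFGS-B", options={"maxiter": 60})
    return -float(objective(res.x))  # leaves engine/model at the optimum


def fit_branch_lengths(
    matrix,
    topology: PhyloTree,
    model_kind: str = "GTR+G",
    max_rounds: int = 8,
    tol: float = 1e-6,
) -> tuple[PhyloTree, SubstitutionModel, float]:
    """Jointly optimize branch lengths, Γ shape and exchangeabilities.

    The topology is fixed; the returned tree is a fitted copy. Deterministic
    given inputs. A matrix with no variation drives every branch to the
    lower bound with a warning.
    """
    tree = topology.copy()
    engine, codes, n_states = _make_engine(matrix, tree)
    freqs = _empirical_freqs(codes, n_states)
    model = SubstitutionModel(
        kind=model_kind,
        exchangeabilities=np.ones(6) if model_kind == "GTR+G" else None,
        freqs=freqs,
        alpha=1.0,
    )
    for node in tree.branch_nodes():
        if node.length <= 0:
            node.length = 0.02

    rev, rates = model.build()
    engine.set_model(rev, rates)
    last = engine.log_likelihood()
    logl = last
    for _ in range(max_rounds):
        logl = _fit_model_params(engine, model)
        logl = engine.optimize_branch_lengths(sweeps_min=1, sweeps_max=4, tol=tol)
        if logl - last < tol:
            break
        last = logl

    if all(n.length <= 10 * MIN_BRANCH_LENGTH for n in tree.branch_nodes()):
        logger.warning("no variation in matrix: all branch lengths at lower bound")
    return tree, model, logl


# ---------------------------------------------------------------------------
# clade rates


def clade_mean_rate(tree: PhyloTree, clade: CalibratedClade) -> float:
    """Mean crown-to-tip path length of the clade divided by its age (subst./site/Ma)."""
    mrca = tree.mrca(list(clade.taxa))
    under = set(tree.leaf_names_under(mrca))
    if under != set(clade.taxa):
        raise ValueError(
            f"clade {clade.name!r} is not monophyletic on this tree; "
            f"MRCA spans {sorted(under)}"
        )
    depths = [tree.path_length(mrca, tree.find_leaf(t)) for t in clade.taxa]
    return float(np.mean(depths)) / clade.age_ma


def _clade_rate_sd(tree: PhyloTree, clade: CalibratedClade) -> float:
    mrca = tree.mrca(list(clade.taxa))
    depths = np.array([tree.path_length(mrca, tree.find_leaf(t)) for t in clade.taxa])
    return float(depths.std(ddof=1)) / clade.age_ma if depths.size > 1 else 0.0


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_rate_test(
    matrix,
    topology: PhyloTree,
    model_kind: str,
    clades: list[CalibratedClade],
    n: int = 500,
    seed: int = 0,
    max_dropped_frac: float = 0.05,
) -> dict[str, RateReport]:
    """Column-bootstrap clade rates and test them against the original estimate.

    Columns of the (concatenated) matrix are resampled uniformly with
    replacement, genome-wide; branch lengths are refit per replicate with the
    model parameters held at the original fit. A two-sided one-sample t-test
    compares the bootstrap sample of each clade's rate to the original value.
    """
    if n < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    fitted_tree, model, _ = fit_branch_lengths(matrix, topology, model_kind)
    original = {c.name: clade_mean_rate(fitted_tree, c) for c in clades}
    spreads = {c.name: _clade_rate_sd(fitted_tree, c) for c in clades}

    codes, taxa, n_states = encode_matrix(matrix)
    n_cols = codes.shape[1]
    patterns, weights = compress_patterns(codes)
    rev, rates = model.build()
    probs = weights / weights.sum()

    boot_rates: dict[str, list[float]] = {c.name: [] for c in clades}
    dropped = 0
    for _rep in range(n):
        w = rng.multinomial(n_cols, probs).astype(float)
        keep = w > 0
        rep_tree = fitted_tree.copy()
        engine = LikelihoodEngine(rep_tree, patterns[:, keep], w[keep], n_states, taxa)
        engine.set_model(rev, rates)
        try:
            engine.optimize_branch_lengths(sweeps_min=1, sweeps_max=3, tol=1e-4)
            for c in clades:
                boot_rates[c.name].append(clade_mean_rate(rep_tree, c))
        except Exception:  # replicate optimization failure
            dropped += 1
    if dropped > max_dropped_frac * n:
        raise RuntimeError(f"{dropped}/{n} bootstrap replicates failed")

    reports = {}
    for c in clades:
        sample = np.asarray(boot_rates[c.name])
        bmean = float(sample.mean())
        bsd = float(sample.std(ddof=1))
        if bsd == 0.0:
            t_stat, p = 0.0, 1.0  # degenerate: no bootstrap variation
        else:
            t_stat, p = stats.ttest_1samp(sample, popmean=original[c.name])
        reports[c.name] = RateReport(
            clade=c.name,
            mean_rate=original[c.name],
            sd=spreads[c.name],
            bootstrap_mean=bmean,
            bootstrap_sd=bsd,
            t=float(t_stat),
            p=float(p),
            n_boot=int(sample.size),
            bootstrap_rates=sample,
        )
    return reports
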