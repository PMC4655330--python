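"""Felsenstein-pruning likelihood engine with discrete-gamma rate mixtures.

Generic over the number of states: the same machinery drives the GTR+Γ
nucleotide model (4 states), the two-state indel model (BIN+Γ) and the
61-state codon model. Reversible rate matrices are eigendecomposed through
the π-symmetrized form so transition probabilities are exact and real.

Branch-length optimization is coordinate-wise Brent. For each branch the
engine assembles the "down" message (conditional likelihood of the subtree
below the branch) and the "up" message (everything else), after which the
log-likelihood as a function of that single branch length is a cheap inner
product — the classic two-pass trick.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees import Node, PhyloTree

__all__ = [
    "discrete_gamma_rates",
    "ReversibleModel",
    "gtr_rate_matrix",
    "binary_rate_matrix",
    "LikelihoodEngine",
    "MIN_BRANCH_LENGTH",
]

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 10.0


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean-normalized category rates of the discretized Gamma(α, α) distribution.

    Categories are equal-probability quantile bins; each category rate is the
    conditional mean within its bin (Yang's mean discretization), renormalized
    so the mixture mean is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    k = n_categories
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X | bin] via the incomplete-gamma identity for Gamma(alpha, 1/alpha)
    upper = gammainc(alpha + 1, edges[1:] * alpha)
    lower = gammainc(alpha + 1, edges[:-1] * alpha)
    rates = k * (upper - lower)
    return rates / rates.mean()


class ReversibleModel:
    """A reversible rate matrix with stationary frequencies, eigendecomposed.

    ``Q`` is normalized to one expected substitution per site per unit branch
    length at stationarity.
    """

    def __init__(self, Q: np.ndarray, freqs: np.ndarray, normalize: bool = True):
        freqs = np.asarray(freqs, dtype=float)
        Q = np.asarray(Q, dtype=float)
        if normalize:
            mu = -np.sum(freqs * np.diag(Q))
            if mu <= 0:
                raise ValueError("degenerate rate matrix")
            Q = Q / mu
        self.Q = Q
        self.freqs = freqs
        sqrt_pi = np.sqrt(freqs)
        # B = D^{1/2} Q D^{-1/2} is symmetric for a reversible Q
        S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)  # symmetrize numerical noise
        eigval, eigvec = np.linalg.eigh(S)
        self._eigval = eigval
        self._left = eigvec.T * sqrt_pi[None, :]
        self._right = eigvec / sqrt_pi[:, None]

    @property
    def n_states(self) -> int:
        return self.freqs.size

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), clipped to be a proper stochastic matrix."""
        P = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        np.clip(P, 1e-300, None, out=P)
        return P

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stack of P(r_k · t) over gamma categories, shape (K, S, S)."""
        return np.stack([self.transition_matrix(r * t) for r in rates])


def gtr_rate_matrix(exchangeabilities: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """GTR Q from 6 exchangeabilities (AC, AG, AT, CG, CT, GT) and base freqs."""
    s = np.asarray(exchangeabilities, dtype=float)
    if s.size != 6 or np.any(s <= 0):
        raise ValueError("need 6 positive exchangeabilities")
    R = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for val, (i, j) in zip(s, pairs):
        R[i, j] = R[j, i] = val
    Q = R * np.asarray(freqs)[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q

def binary_rate_matrix(freqs: np.ndarray) -> np.ndarray:
    """Two-state reversible Q (gain/loss) with stationary freqs."""
    p0, p1 = freqs
    Q = np.array([[-p1, p1], [p0, -p0]], dtype=float)
    return Q


class LikelihoodEngine:
    """Pruning likelihood for one character matrix on one tree.

    ``codes`` holds one integer state per (taxon, pattern); values >=
    ``n_states`` mean fully missing (gap, N, ?). ``weights`` are pattern
    multiplicities from site-pattern compression.
    """

    def __init__(
        self,
        tree: PhyloTree,
        codes: np.ndarray,
        weights: np.ndarray,
        n_states: int,
        taxa: list[str],
    ):
        self.tree = tree
        self.n_states = n_states
        self.weights = np.asarray(weights, dtype=float)
        self.n_patterns = codes.shape[1]
        order = [taxa.index(leaf.name) for leaf in tree.leaves]
        self._tip_partials: dict[int, np.ndarray] = {}
        for leaf, row_idx in zip(tree.leaves, order):
            row = codes[row_idx]
            part = np.ones((self.n_patterns, n_states))
            observed = row < n_states
            part[observed] = 0.0
            part[np.arange(self.n_patterns)[observed], row[observed]] = 1.0
            self._tip_partials[leaf.index] = part
        self.model: ReversibleModel | None = None
        self.rates = np.ones(1)
        #: optional per-branch models (codon free-ratio); falls back to self.model
        self.branch_models: dict[int, ReversibleModel] = {}

    # -- model plumbing -------------------------------------------------------

    def set_model(self, model: ReversibleModel, rates: np.ndarray | None = None) -> None:
        self.model = model
        if rates is not None:
            self.rates = np.asarray(rates, dtype=float)

    def _model_for(self, node: Node) -> ReversibleModel:
        return self.branch_models.get(node.index, self.model)

    def _P(self, node: Node, t: float | None = None) -> np.ndarray:
        length = node.length if t is None else t
        length = max(length, MIN_BRANCH_LENGTH)
        return self._model_for(node).transition_matrices(length, self.rates)

    # -- passes ---------------------------------------------------------------

    def _down_pass(self):
        """Conditional likelihoods below every node, with per-(cat,pattern) log scalers."""
        K = self.rates.size
        down: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        for node in self.tree.postorder:
            if node.is_leaf:
                tp = self._tip_partials[node.index]
                down[node.index] = np.broadcast_to(tp, (K,) + tp.shape).copy()
                logscale[node.index] = np.zeros((K, self.n_patterns))
                continue
            acc = np.ones((K, self.n_patterns, self.n_states))
            ls = np.zeros((K, self.n_patterns))
            for child in node.children:
                P = self._P(child)
                msg = np.matmul(down[child.index], P.transpose(0, 2, 1))
                acc *= msg
                ls += logscale[child.index]
            scale = acc.max(axis=2)
            np.clip(scale, 1e-300, None, out=scale)
            acc /= scale[:, :, None]
            ls += np.log(scale)
            down[node.index] = acc
            logscale[node.index] = ls
        return down, logscale[self.tree.root.index], logscale

    def log_likelihood(self) -> float:
        down, root_ls, _ = self._down_pass()
        return self._root_loglik(down[self.tree.root.index], root_ls)

    def _root_loglik(self, root_partial: np.ndarray, root_ls: np.ndarray) -> float:
        pi = self.model.freqs
        site_l = root_partial @ pi
        np.clip(site_l, 1e-300, None, out=site_l)
        K = self.rates.size
        logl_cat = np.log(site_l) + root_ls  # (K, P)
        m = logl_cat.max(axis=0)
        mix = np.log(np.exp(logl_cat - m[None, :]).sum(axis=0) / K) + m
        return float((self.weights * mix).sum())

    # -- single-branch objective ----------------------------------------------

    def _branch_messages(self, target: Node):
        """(up, down, up_ls, down_ls) messages flanking ``target``'s branch."""
        down, _, logscale = self._down_pass()
        K = self.rates.size
        # "A" message: likelihood of everything above a node, conditioned on
        # the state at that node; A[root] = pi.
        A: dict[int, np.ndarray] = {
            self.tree.root.index: np.broadcast_to(
                self.model.freqs, (K, self.n_patterns, self.n_states)
            ).copy()
        }
        A_ls: dict[int, np.ndarray] = {self.tree.root.index: np.zeros((K, self.n_patterns))}

        # walk only the path down to target
        path = []
        node = target
        while node.parent is not None:
            path.append(node)
            node = node.parent
        path.reverse()
        node = self.tree.root
        for step in path:
            # compute message into `step` from `node`
            acc = A[node.index].copy()
            ls = A_ls[node.index].copy()
            for sib in node.children:
                if sib is step:
                    continue
                P = self._P(sib)
                acc *= np.matmul(down[sib.index], P.transpose(0, 2, 1))
                ls += logscale[sib.index]
            scale = acc.max(axis=2)
            np.clip(scale, 1e-300, None, out=scale)
            acc /= scale[:, :, None]
            ls += np.log(scale)
            if step is target:
                return acc, down[target.index], ls, logscale[target.index]
            P = self._P(step)
            A[step.index] = np.matmul(acc, P)
            A_ls[step.index] = ls
            node = step
        raise AssertionError("target not reached")  # pragma: no cover

    def branch_loglik_fn(self, target: Node):
        """Return f(t) -> logL with only ``target``'s branch length varying."""
        up, down, up_ls, down_ls = self._branch_messages(target)
        ls = up_ls + down_ls
        default_model = self._model_for(target)

        def f(t: float, model: ReversibleModel | None = None) -> float:
            P = (model or default_model).transition_matrices(max(t, MIN_BRANCH_LENGTH), self.rates)
            site = (up * np.matmul(down, P.transpose(0, 2, 1))).sum(axis=2)
            np.clip(site, 1e-300, None, out=site)
            logl_cat = np.log(site) + ls
            m = logl_cat.max(axis=0)
            mix = np.log(np.exp(logl_cat - m[None, :]).sum(axis=0) / self.rates.size) + m
            return float((self.weights * mix).sum())

        return f

    # -- optimization ----------------------------------------------------------

    def optimize_branch_lengths(
        self,
        sweeps_min: int = 3,
        sweeps_max: int = 12,
        tol: float = 1e-6,
        xatol: float = 1e-8,
    ) -> float:
        """Coordinate-wise Brent over all branch lengths; returns final logL."""
        last = self.log_likelihood()
        for sweep in range(sweeps_max):
            for node in self.tree.branch_nodes():
                f = self.branch_loglik_fn(node)
                res = minimize_scalar(
                    lambda t: -f(t),
                    bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                    method="bounded",
                    options={"xatol": xatol, "maxiter": 60},
                )
                if -res.fun >= f(node.length):
                    node.length = float(res.x)
            cur = self.log_likelihood()
            if sweep + 1 >= sweeps_min and cur - last < tol:
                break
            last = cur
        return self.log_likelihood()


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns; returns (unique_codes, weights)."""
    cols, counts = np.unique(codes, axis=1, return_counts=True)
    return cols, counts.astype(float)
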