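"""GTR+Gamma substitution engine.

A minimal but exact continuous-time Markov-chain toolkit for nucleotide
data: transition probabilities via spectral decomposition of the
reversible rate matrix, Felsenstein-pruning log-likelihoods with discrete
gamma rate heterogeneity and per-pattern scaling, coordinate-wise
branch-length optimisation on a fixed topology, pairwise ML distances,
and alignment simulation.

State order is A, C, G, T; exchangeabilities follow the conventional
order AC, AG, AT, CG, CT, GT with GT fixed to 1. The rate matrix is
normalised to one expected substitution per site per unit branch length,
and the mean discrete-gamma category rate is 1, so branch lengths are in
substitutions/site throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc, gammaincinv

from .alignment import Alignment, MISSING_CODE
from . import trees as T

BL_MIN, BL_MAX = 1e-8, 20.0


class ModelError(ValueError):
    pass


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean-of-category discrete gamma rates (equal-probability bins),
    normalised to mean exactly 1."""
    if alpha <= 0:
        raise ModelError(f"gamma shape must be > 0: {alpha}")
    # bin boundaries of Gamma(alpha, mean 1): quantiles at i/ncat
    probs = np.arange(1, ncat) / ncat
    bounds = gammaincinv(alpha, probs)  # scale 1, i.e. x*alpha
    upper = np.concatenate([gammainc(alpha + 1, bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, bounds)])
    rates = ncat * (upper - lower)
    return rates / rates.mean()


@dataclass(frozen=True)
class GTRModel:
    """Time-reversible nucleotide model with optional discrete gamma.

    Parameters
    ----------
    freqs:
        Stationary base frequencies (A,C,G,T), summing to 1.
    rates:
        Exchangeabilities (AC, AG, AT, CG, CT, GT); GT conventionally 1.
    alpha:
        Discrete-gamma shape; ``None`` disables rate heterogeneity.
    ncat:
        Number of gamma categories (ignored when ``alpha`` is None).
    """

    freqs: tuple[float, float, float, float]
    rates: tuple[float, float, float, float, float, float] = (1.0,) * 6
    alpha: float | None = None
    ncat: int = 4

    def __post_init__(self):
        f = np.asarray(self.freqs, float)
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1) > 1e-8:
            raise ModelError(f"invalid base frequencies: {self.freqs}")
        r = np.asarray(self.rates, float)
        if r.shape != (6,) or np.any(r <= 0):
            raise ModelError(f"invalid exchangeabilities: {self.rates}")
        if self.alpha is not None and self.alpha <= 0:
            raise ModelError(f"invalid gamma shape: {self.alpha}")

    @classmethod
    def jc69(cls, alpha: float | None = None, ncat: int = 4) -> "GTRModel":
        return cls(freqs=(0.25,) * 4, alpha=alpha, ncat=ncat)

    @property
    def q_matrix(self) -> np.ndarray:
        """Rate matrix normalised to mean rate 1 (rows sum to 0)."""
        pi = np.asarray(self.freqs)
        s = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), r in zip(idx, self.rates):
            s[i, j] = s[j, i] = r
        q = s * pi[None, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def _eig(self):
        """Spectral decomposition via symmetrisation (cached)."""
        if not hasattr(self, "_eig_cache"):
            pi = np.asarray(self.freqs)
            d = np.sqrt(pi)
            b = self.q_matrix * d[:, None] / d[None, :]
            b = 0.5 * (b + b.T)
            lam, v = np.linalg.eigh(b)
            left = v.T * d[None, :]          # V' D^{1/2}
            right = v / d[:, None]           # D^{-1/2} V
            object.__setattr__(self, "_eig_cache", (lam, right, left))
        return self._eig_cache

    @property
    def gamma_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.array([1.0])
        return discrete_gamma_rates(self.alpha, self.ncat)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(rate * t); rows sum to 1."""
        if t < 0:
            raise ModelError(f"negative branch length: {t}")
        lam, right, left = self._eig()
        # eigenvalues of Q are <= 0; clip numerical noise so huge t stays finite
        p = (right * np.exp(np.minimum(lam * rate * t, 0.0))[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(r_c * t) over gamma categories, shape (ncat, 4, 4)."""
        if t < 0:
            raise ModelError(f"negative branch length: {t}")
        lam, right, left = self._eig()
        if not hasattr(self, "_gr_cache"):
            object.__setattr__(self, "_gr_cache", self.gamma_rates)
        e = np.exp(np.minimum(lam[None, :] * (self._gr_cache * t)[:, None],
                              0.0))  # (ncat,4)
        p = (right[None, :, :] * e[:, None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=2, keepdims=True)


def empirical_frequencies(aln: Alignment, pseudocount: float = 1.0
                          ) -> np.ndarray:
    codes = aln.codes()
    counts = np.bincount(codes[codes < 4].ravel(), minlength=4).astype(float)
    counts += pseudocount
    return counts / counts.sum()


def empirical_exchangeabilities(aln: Alignment) -> np.ndarray:
    """Moment-style exchangeabilities from pairwise mismatch counts:
    s_ij proportional to observed i<->j mismatch frequency / (pi_i pi_j),
    GT rescaled to 1."""
    codes = aln.codes()
    n = codes.shape[0]
    pair_counts = np.zeros((4, 4))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a < 4) & (b < 4)
            np.add.at(pair_counts, (a[ok], b[ok]), 1.0)
    pair_counts = pair_counts + pair_counts.T
    pi = empirical_frequencies(aln)
    idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    s = np.array([pair_counts[i, j] / (pi[i] * pi[j]) for i, j in idx])
    s += 1e-6 * s.max() + 1e-12
    return s / s[5]


# ======================================================================
# Pruning likelihood
# ======================================================================

@dataclass
class LikelihoodResult:
    log_likelihood: float
    per_site_log_likelihoods: np.ndarray
    branch_lengths: dict[frozenset, float] | None = None
    n_sweeps: int = 0


class TreeLikelihood:
    """Felsenstein-pruning likelihood of an alignment on a fixed topology.

    The tree is derooted to a trifurcating seed; branch lengths are taken
    from the tree and may subsequently be re-optimised in place. Gaps and
    ``N`` are treated as fully ambiguous. Per-pattern scaling keeps the
    computation exact in log space.
    """

    def __init__(self, aln: Alignment, tree, model: GTRModel,
                 use_tree_lengths: bool = True, init_length: float = 0.1):
        leaves = T.leaf_labels(tree)
        common = [t for t in aln.taxa if t in leaves]
        if len(common) < 3:
            raise ModelError("fewer than 3 taxa shared by alignment and tree")
        if set(common) != leaves:
            tree = T.restrict_to_taxa(tree, common)
        aln = aln.select_taxa(common)
        self.model = model
        self.taxa = common

        codes = aln.codes()
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True)
        self._pat = patterns.T          # (n_taxa, npat)
        self._weights = counts.astype(float)
        self._site_to_pat = inverse
        self.n_sites = aln.length

        t = T._deroot(tree)
        nodes = list(t.postorder_node_iter())
        self._n = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self._children: list[list[int]] = [[] for _ in nodes]
        self._parent = np.full(self._n, -1)
        self._brlen = np.zeros(self._n)
        self._leaf_row = np.full(self._n, -1)
        row = {lab: i for i, lab in enumerate(common)}
        self._split_of_node: list[frozenset | None] = [None] * self._n
        leafset = frozenset(common)
        below: dict[int, frozenset] = {}
        for nd in nodes:
            i = index[id(nd)]
            if nd.is_leaf():
                self._leaf_row[i] = row[nd.taxon.label]
                below[i] = frozenset([nd.taxon.label])
            else:
                self._children[i] = [index[id(c)] for c in nd.child_nodes()]
                below[i] = frozenset().union(*(below[c] for c in
                                               self._children[i]))
            if nd.parent_node is not None:
                self._parent[i] = index[id(nd.parent_node)]
                self._brlen[i] = max(
                    (nd.edge.length if use_tree_lengths and
                     nd.edge.length is not None else init_length), BL_MIN)
                self._split_of_node[i] = below[i]
        self._root = index[id(t.seed_node)]
        self._order = [index[id(nd)] for nd in nodes]  # postorder
        self._preorder = [i for i in reversed(self._order)
                          if self._parent[i] >= 0]

        ncat = len(model.gamma_rates)
        npat = len(self._weights)
        self._tip_partial = np.zeros((4, npat, 4))
        eye = np.vstack([np.eye(4), np.ones(4)])
        self._tip_cache = {}
        self._ncat, self._npat = ncat, npat
        self._eye5 = eye

    def with_model(self, model: GTRModel, branch_scale: float = 1.0
                   ) -> "TreeLikelihood":
        """Shallow copy sharing the compressed data and tree structure but
        evaluating under a different model (and optional global rescaling
        of the branch lengths) - cheap enough for direct-search fitting."""
        import copy as _copy
        new = _copy.copy(self)
        new.model = model
        new._brlen = np.clip(self._brlen * branch_scale, BL_MIN, BL_MAX)
        return new

    # -- low-level passes -------------------------------------------------
    def _tip(self, i: int) -> np.ndarray:
        """(npat, 4) indicator partials for leaf node i."""
        if i not in self._tip_cache:
            self._tip_cache[i] = self._eye5[self._pat[self._leaf_row[i]]]
        return self._tip_cache[i]

    def _msg(self, i: int, D, t=None) -> np.ndarray:
        """P(t_i) applied to node i's down partial: (ncat, npat, 4)."""
        P = self.model.transition_matrices(self._brlen[i] if t is None else t)
        pt = np.ascontiguousarray(np.transpose(P, (0, 2, 1)))
        if self._leaf_row[i] >= 0:
            return self._tip(i)[None, :, :] @ pt
        return D[i] @ pt

    def _down_pass(self):
        """Post-order conditional likelihoods for internal nodes, with
        per-pattern log scalers."""
        D = [None] * self._n
        logs = np.zeros((self._n, self._npat))
        for i in self._order:
            if self._leaf_row[i] >= 0:
                continue
            part = None
            sc = np.zeros(self._npat)
            for c in self._children[i]:
                m = self._msg(c, D)
                part = m if part is None else part * m
                if self._leaf_row[c] < 0:
                    sc += logs[c]
            mx = part.max(axis=(0, 2))
            mx[mx <= 0] = 1.0
            part /= mx[None, :, None]
            D[i] = part
            logs[i] = sc + np.log(mx)
        return D, logs

    def _root_lnl(self, D, logs):
        pi = np.asarray(self.model.freqs)
        like = (D[self._root] @ pi).mean(axis=0)  # (npat,)
        per_pat = np.log(like) + logs[self._root]
        return float(per_pat @ self._weights), per_pat

    def log_likelihood(self) -> float:
        D, logs = self._down_pass()
        lnl, _ = self._root_lnl(D, logs)
        return lnl

    def result(self, with_lengths: bool = False, n_sweeps: int = 0
               ) -> LikelihoodResult:
        D, logs = self._down_pass()
        lnl, per_pat = self._root_lnl(D, logs)
        bl = None
        if with_lengths:
            bl = {self._split_of_node[i]: float(self._brlen[i])
                  for i in range(self._n) if self._parent[i] >= 0}
        return LikelihoodResult(lnl, per_pat[self._site_to_pat], bl, n_sweeps)

    @property
    def branch_lengths(self) -> np.ndarray:
        return self._brlen.copy()

    # -- branch-length optimisation --------------------------------------
    def _edge_lnl_fn(self, i, U, ulog, D, logs):
        pi = np.asarray(self.model.freqs)
        down_is_leaf = self._leaf_row[i] >= 0
        dlog = 0.0 if down_is_leaf else logs[i]
        w = self._weights

        def f(t):
            m = self._msg(i, D, t=t)
            like = (U * m).sum(axis=2).mean(axis=0)
            like = np.maximum(like, 1e-300)
            return float(w @ (np.log(like) + ulog + dlog))
        return f

    def _optimize_edge(self, i, U, ulog, D, logs, tol=1e-6):
        f = self._edge_lnl_fn(i, U, ulog, D, logs)
        t0 = self._brlen[i]

        lo, hi = math.log(BL_MIN), math.log(BL_MAX)

        def nf(x):
            return -f(math.exp(min(max(x, lo), hi)))
        res = minimize_scalar(
            nf, bracket=(math.log(t0) - 0.7, math.log(t0)),
            method="brent", options={"xtol": 1e-3, "maxiter": 24})
        t_new = float(np.clip(math.exp(res.x), BL_MIN, BL_MAX))
        if -res.fun >= f(t0) - tol:
            self._brlen[i] = t_new

    def optimize_branch_lengths(self, max_rounds: int = 20,
                                lnl_tol: float = 1e-4) -> LikelihoodResult:
        """Coordinate-wise Brent optimisation of all branch lengths.

        Each sweep recomputes conditional likelihoods, then updates edges
        in pre-order using outside/inside partial vectors; a sweep that
        fails to improve the exact log-likelihood is rolled back, so the
        reported value is non-decreasing across sweeps.
        """
        pi = np.asarray(self.model.freqs)
        best = self.log_likelihood()
        if not np.isfinite(best):
            raise ModelError("non-finite likelihood at starting lengths")
        sweeps = 0
        for _ in range(max_rounds):
            prev_bl = self._brlen.copy()
            D, logs = self._down_pass()
            U = [None] * self._n
            ulog = [None] * self._n
            # children of the seed
            rc = self._children[self._root]
            msgs = {c: self._msg(c, D) for c in rc}
            for i in self._preorder:
                p = self._parent[i]
                if p == self._root:
                    part = pi[None, None, :] * np.ones((self._ncat,
                                                        self._npat, 4))
                    sc = np.zeros(self._npat)
                    for c in rc:
                        if c == i:
                            continue
                        part = part * msgs[c]
                        if self._leaf_row[c] < 0:
                            sc += logs[c]
                else:
                    Pp = self.model.transition_matrices(self._brlen[p])
                    part = U[p] @ Pp
                    sc = ulog[p].copy()
                    for c in self._children[p]:
                        if c == i:
                            continue
                        part = part * self._msg(c, D)
                        if self._leaf_row[c] < 0:
                            sc += logs[c]
                mx = part.max(axis=(0, 2))
                mx[mx <= 0] = 1.0
                part /= mx[None, :, None]
                U[i], ulog[i] = part, sc + np.log(mx)
                self._optimize_edge(i, U[i], ulog[i], D, logs)
            sweeps += 1
            cur = self.log_likelihood()
            if cur < best:
                self._brlen = prev_bl
                break
            gain, best = cur - best, cur
            if gain < lnl_tol:
                break
        res = self.result(with_lengths=True, n_sweeps=sweeps)
        return res


def tree_log_likelihood(aln: Alignment, tree, model: GTRModel
                        ) -> LikelihoodResult:
    """Log-likelihood of ``aln`` on ``tree`` (lengths taken from the tree)."""
    return TreeLikelihood(aln, tree, model).result()


def optimize_branch_lengths(aln: Alignment, topology, model: GTRModel,
                            **kw) -> LikelihoodResult:
    tl = TreeLikelihood(aln, topology, model)
    return tl.optimize_branch_lengths(**kw)


# ======================================================================
# Pairwise distances
# ======================================================================

SATURATED = math.inf  # sentinel for distances beyond the correctable range


def p_distance(aln: Alignment, taxon1: str, taxon2: str) -> float:
    c = aln.select_taxa([taxon1, taxon2]).codes()
    ok = (c[0] < 4) & (c[1] < 4)
    if not ok.any():
        raise ModelError(f"no shared ungapped columns: {taxon1}/{taxon2}")
    return float(np.mean(c[0][ok] != c[1][ok]))


def p_distance_matrix(aln: Alignment) -> np.ndarray:
    """All-pairs uncorrected distance on pairwise-shared ungapped columns
    (NaN when a pair shares no columns); order follows ``aln.taxa``."""
    c = aln.codes()
    n = c.shape[0]
    out = np.zeros((n, n))
    ok = c < 4
    for i in range(n):
        for j in range(i + 1, n):
            m = ok[i] & ok[j]
            tot = int(m.sum())
            out[i, j] = out[j, i] = (
                np.mean(c[i][m] != c[j][m]) if tot else np.nan)
    return out


def jc_distance_from_p(p: float) -> float:
    if p >= 0.75:
        return SATURATED
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_distance(aln: Alignment, taxon1: str, taxon2: str,
                      model_family: str = "GTR",
                      model: GTRModel | None = None) -> float:
    """ML distance in substitutions/site between two aligned sequences.

    ``JC``: closed-form Jukes-Cantor correction of the p-distance
    (saturated, p >= 3/4, returns ``inf``). ``GTR``: one-dimensional ML
    branch-length fit under a two-leaf tree; the model defaults to
    alignment-wide empirical frequencies and exchangeabilities.
    """
    if model_family.upper() == "JC":
        return jc_distance_from_p(p_distance(aln, taxon1, taxon2))
    if model_family.upper() != "GTR":
        raise ModelError(f"unknown model family: {model_family}")
    if model is None:
        model = GTRModel(freqs=tuple(empirical_frequencies(aln)),
                         rates=tuple(empirical_exchangeabilities(aln)))
    c = aln.select_taxa([taxon1, taxon2]).codes()
    ok = (c[0] < 4) & (c[1] < 4)
    if not ok.any():
        raise ModelError(f"no shared ungapped columns: {taxon1}/{taxon2}")
    counts = np.zeros((4, 4))
    np.add.at(counts, (c[0][ok], c[1][ok]), 1.0)
    if counts.sum() == np.trace(counts):
        return 0.0
    pi = np.asarray(model.freqs)

    def nll(logt):
        p = sum(model.transition_matrix(math.exp(logt), r)
                for r in model.gamma_rates) / len(model.gamma_rates)
        m = pi[:, None] * p
        return -float((counts * np.log(np.maximum(m, 1e-300))).sum())

    res = minimize_scalar(nll, bracket=(math.log(0.02), math.log(0.5)),
                          method="brent", options={"xtol": 1e-6})
    return float(np.clip(math.exp(res.x), 0.0, BL_MAX))


# ======================================================================
# Model fitting
# ======================================================================

def fit_model(aln: Alignment, tree, ncat: int = 4,
              estimate_exchangeabilities: bool = False,
              maxiter: int = 60) -> GTRModel:
    """Per-locus GTR+Gamma fit on a fixed gene tree.

    Frequencies are empirical counts; exchangeabilities start from the
    moment estimator (optionally refined by Nelder-Mead ML); the gamma
    shape and a global branch-scale factor are optimised jointly by
    direct search. The fitted model is meant to be held fixed when
    re-scoring alternative topologies of the same locus.
    """
    freqs = tuple(empirical_frequencies(aln))
    exch = empirical_exchangeabilities(aln)
    base = TreeLikelihood(aln, tree, GTRModel(freqs=freqs, alpha=1.0,
                                              ncat=ncat))

    def nll_core(alpha, scale, rates):
        try:
            m = GTRModel(freqs=freqs, rates=tuple(rates), alpha=alpha,
                         ncat=ncat)
            return -base.with_model(m, branch_scale=scale).log_likelihood()
        except (ModelError, FloatingPointError):
            return 1e12

    def nll2(x):
        return nll_core(math.exp(x[0]), math.exp(x[1]), exch)

    res = minimize(nll2, x0=[0.0, 0.0], method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-2,
                            "fatol": 1e-3})
    alpha, scale = math.exp(res.x[0]), math.exp(res.x[1])
    if estimate_exchangeabilities:
        def nll_full(x):
            rates = np.concatenate([np.exp(x[2:]), [1.0]])
            return nll_core(math.exp(x[0]), math.exp(x[1]), rates)
        x0 = np.concatenate([res.x, np.log(np.maximum(exch[:5], 1e-4))])
        res2 = minimize(nll_full, x0=x0, method="Nelder-Mead",
                        options={"maxiter": 4 * maxiter, "xatol": 1e-2,
                                 "fatol": 1e-3})
        alpha, scale = math.exp(res2.x[0]), math.exp(res2.x[1])
        exch = np.concatenate([np.exp(res2.x[2:]), [1.0]])
    return GTRModel(freqs=freqs, rates=tuple(exch), alpha=alpha, ncat=ncat)


# ======================================================================
# Simulation
# ======================================================================

def simulate_alignment(tree, model: GTRModel, n_sites: int,
                       site_rate_multipliers: Sequence[float] | None = None,
                       rng: np.random.Generator | int | None = None,
                       codon_frame: bool | None = None) -> Alignment:
    """Evolve ``n_sites`` i.i.d. sites along ``tree`` under ``model``.

    ``site_rate_multipliers`` may be per-site (length ``n_sites``) or a
    length-3 codon-position pattern tiled across the alignment. Discrete
    gamma categories, when the model has them, are drawn per site.
    """
    rng = np.random.default_rng(rng)
    if site_rate_multipliers is None:
        mult = np.ones(n_sites)
    else:
        m = np.asarray(site_rate_multipliers, float)
        mult = np.tile(m, n_sites // 3 + 1)[:n_sites] if m.size == 3 else m
        if mult.size != n_sites:
            raise ModelError("site_rate_multipliers length mismatch")
    gr = model.gamma_rates
    cat = rng.integers(len(gr), size=n_sites)
    rates = gr[cat] * mult

    pi = np.asarray(model.freqs)
    t = T._deroot(tree)
    states: dict[int, np.ndarray] = {}
    states[id(t.seed_node)] = rng.choice(4, size=n_sites, p=pi)
    taxa, seqs = [], []
    uniq_rates, inv = np.unique(rates, return_inverse=True)
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            continue
        bl = nd.edge.length or 0.0
        parent = states[id(nd.parent_node)]
        child = np.empty(n_sites, dtype=np.int64)
        u = rng.random(n_sites)
        for k, r in enumerate(uniq_rates):
            sel = inv == k
            if not sel.any():
                continue
            P = model.transition_matrix(bl, rate=float(r))
            cum = np.cumsum(P, axis=1)
            child[sel] = (u[sel, None] > cum[parent[sel]]).sum(axis=1)
        states[id(nd)] = child
        if nd.is_leaf():
            taxa.append(nd.taxon.label)
            seqs.append("".join("ACGT"[s] for s in child))
    if codon_frame is None:
        codon_frame = (site_rate_multipliers is not None
                       and np.asarray(site_rate_multipliers).size == 3
                       and n_sites % 3 == 0)
    return Alignment(taxa, seqs, codon_frame=codon_frame)
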