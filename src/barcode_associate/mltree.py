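"""Maximum-likelihood tree scoring and light topology search.

Likelihoods are computed by Felsenstein pruning over unique site patterns,
with transition probabilities from the eigendecomposition of a reversible
GTR-family rate matrix scaled to mean rate 1, and among-site rate
heterogeneity by four equal-probability discrete-gamma categories using
category-mean rates. Gaps and ambiguity codes are fully missing states at a
leaf. The supported model set is the nested family JC, K2P, HKY, TIM2 —
TIM2 being GTR constrained by r_AC = r_AT and r_CG = r_GT with unequal base
frequencies, the model used for the tree inference this pipeline mirrors.

Tree search is deliberately light: a neighbor-joining starting tree,
coordinate-wise branch-length optimization, and greedy nearest-neighbor
interchange accepting the best improving move until no move improves the
log-likelihood beyond tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as _gamma_dist

from barcode_associate.distmat import build_matrix, matrix_from_encoded
from barcode_associate.njtree import nj
from barcode_associate.records import MISSING, Dataset
from barcode_associate.tree import PhyloTree, TreeError

logger = logging.getLogger(__name__)

#: Exchangeability parameter order (GTR convention).
EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")

MODEL_NAMES = ("JC", "K2P", "HKY", "TIM2")

MIN_BRLEN = 1e-6
MAX_BRLEN = 10.0
DEFAULT_LNL_TOL = 1e-4
DEFAULT_ALPHA = 1.0

_FLAT = np.full(4, 0.25)


@dataclass
class SubstitutionModel:
    """A reversible nucleotide substitution model, optionally with +G4 rates.

    ``exchangeabilities`` follow :data:`EXCH_ORDER`; ``gamma_alpha=None``
    means homogeneous rates. The rate matrix is always rescaled so the mean
    substitution rate at stationarity is 1, making branch lengths expected
    substitutions per site.
    """

    name: str
    base_freqs: np.ndarray
    exchangeabilities: np.ndarray
    gamma_alpha: float | None = None
    n_categories: int = 4
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.base_freqs.shape != (4,) or np.any(self.base_freqs <= 0):
            raise ValueError("base_freqs must be 4 positive values")
        if abs(self.base_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("base_freqs must sum to 1")
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
            raise ValueError("exchangeabilities must be 6 positive values")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be positive")
        self._check_constraints()

    def _check_constraints(self) -> None:
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        if self.name == "JC":
            if not (np.allclose(self.exchangeabilities, self.exchangeabilities[0])
                    and np.allclose(self.base_freqs, _FLAT)):
                raise ValueError("JC requires equal rates and equal frequencies")
        elif self.name == "K2P":
            if not (np.isclose(ag, ct) and np.allclose([ac, at, cg, gt], ac)
                    and np.allclose(self.base_freqs, _FLAT)):
                raise ValueError("K2P requires one ts and one tv rate, equal frequencies")
        elif self.name == "HKY":
            if not (np.isclose(ag, ct) and np.allclose([ac, at, cg, gt], ac)):
                raise ValueError("HKY requires one ts and one tv rate")
        elif self.name == "TIM2":
            if not (np.isclose(ac, at) and np.isclose(cg, gt)):
                raise ValueError("TIM2 requires r_AC = r_AT and r_CG = r_GT")
        else:
            raise ValueError(f"unknown model name {self.name!r}")

    # -- factories -----------------------------------------------------

    @classmethod
    def jc(cls, gamma_alpha: float | None = None) -> "SubstitutionModel":
        return cls("JC", _FLAT.copy(), np.ones(6), gamma_alpha)

    @classmethod
    def k2p(cls, kappa: float = 2.0, gamma_alpha: float | None = None) -> "SubstitutionModel":
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls("K2P", _FLAT.copy(), ex, gamma_alpha)

    @classmethod
    def hky(cls, base_freqs, kappa: float = 2.0, gamma_alpha: float | None = None) -> "SubstitutionModel":
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls("HKY", np.asarray(base_freqs, float), ex, gamma_alpha)

    @classmethod
    def tim2(
        cls,
        base_freqs,
        r_ac: float = 1.0,
        r_ag: float = 4.0,
        r_ct: float = 4.0,
        gamma_alpha: float | None = None,
    ) -> "SubstitutionModel":
        # r_CG = r_GT = 1 fixed for identifiability; r_AT = r_AC by constraint
        ex = np.array([r_ac, r_ag, r_ac, 1.0, r_ct, 1.0])
        return cls("TIM2", np.asarray(base_freqs, float), ex, gamma_alpha)

    # -- rate matrix ---------------------------------------------------

    def q_matrix(self) -> np.ndarray:
        """GTR rate matrix scaled to mean rate 1."""
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        R = np.array(
            [
                [0.0, ac, ag, at],
                [ac, 0.0, cg, ct],
                [ag, cg, 0.0, gt],
                [at, ct, gt, 0.0],
            ]
        )
        Q = R * self.base_freqs[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(self.base_freqs, np.diag(Q))
        return Q / mu

    def _eigendecomposition(self):
        if self._eig is None:
            Q = self.q_matrix()
            sq = np.sqrt(self.base_freqs)
            B = (Q * sq[:, None]) / sq[None, :]
            w, V = np.linalg.eigh((B + B.T) / 2.0)
            left = V.T * sq[None, :]  # V^T D^{1/2}
            right = V / sq[:, None]  # D^{-1/2} V
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are 'from', columns 'to'."""
        if t < 0:
            raise ValueError("negative time")
        w, right, left = self._eigendecomposition()
        P = (right * np.exp(w * t)[None, :]) @ left
        return np.clip(P, 0.0, None)

    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (mean-rate method, mean 1)."""
        if self.gamma_alpha is None:
            return np.ones(1)
        a = self.gamma_alpha
        k = self.n_categories
        bounds = _gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        upper = np.append(gammainc(a + 1.0, bounds * a), 1.0)
        lower = np.insert(gammainc(a + 1.0, bounds * a), 0, 0.0)
        return k * (upper - lower)

    def n_free_parameters(self, n_taxa: int) -> int:
        """Free parameters: branch lengths + substitution + gamma shape."""
        branches = 2 * n_taxa - 3 if n_taxa >= 3 else 1
        subst = {"JC": 0, "K2P": 1, "HKY": 1 + 3, "TIM2": 3 + 3}[self.name]
        return branches + subst + (0 if self.gamma_alpha is None else 1)


@dataclass
class LikelihoodResult:
    """Fitted log-likelihood with the tree and model that produced it."""

    log_likelihood: float
    tree: PhyloTree
    model: SubstitutionModel
    n_free_parameters: int


def empirical_base_freqs(ds: Dataset) -> np.ndarray:
    """Base frequencies counted from unambiguous sites, pseudocount-smoothed."""
    X = ds.encoded()
    counts = np.bincount(X[X != MISSING], minlength=4).astype(float) + 1.0
    return counts / counts.sum()


class PatternLikelihood:
    """Pruning-based likelihood engine over compressed site patterns.

    Leaf partials and pattern counts are computed once per alignment; the
    model and tree vary per call, which is what branch-length optimization,
    NNI search and parameter fitting need.
    """

    def __init__(self, X: np.ndarray, ids: list[str]):
        if X.ndim != 2 or X.shape[0] != len(ids):
            raise ValueError("X must be (n_records, n_sites) matching ids")
        patterns, counts = np.unique(X, axis=1, return_counts=True)
        self.counts = counts.astype(float)
        self.n_sites = X.shape[1]
        self.npat = patterns.shape[1]
        self.leaf_partials: dict[str, np.ndarray] = {}
        for row, sid in zip(patterns, ids):
            part = np.zeros((self.npat, 4))
            known = row != MISSING
            part[known, row[known]] = 1.0
            part[~known, :] = 1.0
            self.leaf_partials[sid] = part

    @classmethod
    def from_dataset(cls, ds: Dataset) -> "PatternLikelihood":
        return cls(ds.encoded(), ds.ids)

    def _cat_matrices(self, model: SubstitutionModel, t: float, rates: np.ndarray) -> np.ndarray:
        return np.stack([model.transition_matrix(t * r) for r in rates])

    def _subtree_partial(
        self, tree: PhyloTree, model: SubstitutionModel, root: int, blocked: int | None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Conditional likelihoods of the data on root's side of (root, blocked).

        Returns (partials (ncat, npat, 4), logscale (ncat, npat)); the partial
        conditions on the state at ``root``. ``blocked=None`` covers the whole
        tree.
        """
        rates = model.category_rates()
        ncat = len(rates)
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros((ncat, self.npat))
        stack = [(root, blocked, False)]
        order: list[tuple[int, int | None]] = []
        while stack:
            node, parent, expanded = stack.pop()
            if expanded:
                order.append((node, parent))
                continue
            stack.append((node, parent, True))
            for nb in sorted(tree.adj[node]):
                if nb != parent:
                    stack.append((nb, node, False))
        for node, parent in order:
            if tree.is_leaf(node):
                base = self.leaf_partials[tree.leaf_name[node]]
                arr = np.repeat(base[None, :, :], ncat, axis=0)
            else:
                arr = np.ones((ncat, self.npat, 4))
            for child in tree.adj[node]:
                if child == parent:
                    continue
                Ps = self._cat_matrices(model, tree.adj[node][child], rates)
                cp = partial.pop(child)
                arr = arr * np.matmul(cp, Ps.transpose(0, 2, 1))
            if not tree.is_leaf(node):
                mx = arr.max(axis=2)
                mx = np.where(mx > 0.0, mx, 1.0)
                arr /= mx[:, :, None]
                logscale += np.log(mx)
            partial[node] = arr
        return partial[root], logscale

    def lnl(self, tree: PhyloTree, model: SubstitutionModel) -> float:
        """Log-likelihood of the tree under the model (no optimization)."""
        if set(tree.taxa) != set(self.leaf_partials):
            raise TreeError("tree leaves do not match alignment records")
        ncat = len(model.category_rates())
        internal = [v for v in tree.adj if not tree.is_leaf(v)]
        root = max(internal, key=lambda v: (len(tree.adj[v]), -v)) if internal else tree.node_of(tree.taxa[0])
        arr, logscale = self._subtree_partial(tree, model, root, None)
        site_cat = arr @ model.base_freqs  # (ncat, npat)
        with np.errstate(divide="ignore"):
            log_site = logsumexp(
                np.log(1.0 / ncat) + logscale + np.log(site_cat), axis=0
            )
        return float(np.dot(self.counts, log_site))

    # -- optimization --------------------------------------------------

    def optimize_edge(
        self, tree: PhyloTree, a: int, b: int, model: SubstitutionModel
    ) -> float:
        """Optimize one branch length in place; returns the new lnL.

        The subtree partials on both sides of the edge are computed once;
        each trial length then costs only one transition-matrix contraction
        (valid for reversible models, where the root can sit anywhere).
        """
        rates = model.category_rates()
        ncat = len(rates)
        pi = model.base_freqs
        pa, lsa = self._subtree_partial(tree, model, a, b)
        pb, lsb = self._subtree_partial(tree, model, b, a)
        base = np.log(1.0 / ncat) + lsa + lsb

        pa_pi = pa * pi[None, None, :]

        def neg(t: float) -> float:
            Ps = self._cat_matrices(model, t, rates)
            # site L = sum_xy pi_x pa_x P_xy pb_y, per category
            site_cat = (pa_pi * np.matmul(pb, Ps.transpose(0, 2, 1))).sum(axis=2)
            with np.errstate(divide="ignore"):
                log_site = logsumexp(base + np.log(site_cat), axis=0)
            return -float(np.dot(self.counts, log_site))

        old_lnl = -neg(tree.adj[a][b])
        res = minimize_scalar(
            neg, bounds=(MIN_BRLEN, MAX_BRLEN), method="bounded",
            options={"xatol": 1e-5, "maxiter": 40},
        )
        if -float(res.fun) < old_lnl:
            return old_lnl  # keep the old length: optimizer found no gain
        tree.set_branch_length(a, b, float(res.x))
        return -float(res.fun)

    def optimize_branches(
        self,
        tree: PhyloTree,
        model: SubstitutionModel,
        tol: float = DEFAULT_LNL_TOL,
        max_sweeps: int = 20,
    ) -> float:
        """Coordinate-wise branch-length optimization; monotone in lnL."""
        for a, b, ln in tree.edges():
            if ln < MIN_BRLEN:
                tree.set_branch_length(a, b, MIN_BRLEN)
        best = self.lnl(tree, model)
        for sweep in range(max_sweeps):
            prev = best
            for a, b, _ in sorted(tree.edges()):
                best = self.optimize_edge(tree, a, b, model)
            if best - prev < tol:
                break
        else:
            logger.warning(
                "branch-length optimization: no convergence in %d sweeps", max_sweeps
            )
        return best

    def nni_search(
        self,
        tree: PhyloTree,
        model: SubstitutionModel,
        tol: float = DEFAULT_LNL_TOL,
        max_rounds: int = 25,
    ) -> tuple[PhyloTree, float]:
        """Greedy best-improvement NNI with local edge re-optimization."""
        current = tree.copy()
        best = self.optimize_branches(current, model, tol=tol)
        for _ in range(max_rounds):
            candidates = []
            for a, b in _internal_edges(current):
                for alt in (0, 1):
                    cand = current.copy()
                    _apply_nni(cand, a, b, alt)
                    lnl = self.optimize_edge(cand, a, b, model)
                    candidates.append((lnl, (a, b, alt), cand))
            if not candidates:
                break
            lnl_best, _, cand_best = max(candidates, key=lambda c: (c[0], c[1]))
            if lnl_best <= best + tol:
                break
            current = cand_best
            best = self.optimize_branches(current, model, tol=tol)
        return current, best


def _internal_edges(tree: PhyloTree) -> list[tuple[int, int]]:
    """Internal (non-pendant) edges in deterministic order."""
    return sorted(
        (a, b)
        for a, b, _ in tree.edges()
        if not tree.is_leaf(a) and not tree.is_leaf(b)
    )


def _apply_nni(tree: PhyloTree, u: int, v: int, alt: int) -> None:
    """Swap one subtree across internal edge (u, v); alt selects which."""
    a_side = sorted(n for n in tree.adj[u] if n != v)
    b_side = sorted(n for n in tree.adj[v] if n != u)
    if len(a_side) < 2 or len(b_side) < 2:
        raise TreeError("NNI requires an internal edge between degree-3 nodes")
    x = a_side[1]
    y = b_side[alt]
    lx = tree.adj[u][x]
    ly = tree.adj[v][y]
    tree.remove_edge(u, x)
    tree.remove_edge(v, y)
    tree.add_edge(u, y, ly)
    tree.add_edge(v, x, lx)


# -- public operations ------------------------------------------------


def site_log_likelihood(
    tree: PhyloTree, ds: Dataset, model: SubstitutionModel
) -> LikelihoodResult:
    """Log-likelihood of a fixed tree (no optimization)."""
    engine = PatternLikelihood.from_dataset(ds)
    lnl = engine.lnl(tree, model)
    return LikelihoodResult(lnl, tree, model, model.n_free_parameters(len(ds)))


def optimize_branch_lengths(
    tree: PhyloTree,
    ds: Dataset,
    model: SubstitutionModel,
    tol: float = DEFAULT_LNL_TOL,
    max_sweeps: int = 20,
) -> LikelihoodResult:
    """Optimize all branch lengths of a copy of ``tree``."""
    engine = PatternLikelihood.from_dataset(ds)
    fitted = tree.copy()
    lnl = engine.optimize_branches(fitted, model, tol=tol, max_sweeps=max_sweeps)
    return LikelihoodResult(lnl, fitted, model, model.n_free_parameters(len(ds)))


def nni_search(
    start: PhyloTree,
    ds: Dataset,
    model: SubstitutionModel,
    tol: float = DEFAULT_LNL_TOL,
    max_rounds: int = 25,
) -> LikelihoodResult:
    """Greedy NNI search from a starting tree; lnL never decreases."""
    engine = PatternLikelihood.from_dataset(ds)
    tree, lnl = engine.nni_search(start, model, tol=tol, max_rounds=max_rounds)
    return LikelihoodResult(lnl, tree, model, model.n_free_parameters(len(ds)))


def ml_tree(
    ds: Dataset,
    model: SubstitutionModel,
    do_nni: bool = True,
    tol: float = DEFAULT_LNL_TOL,
) -> LikelihoodResult:
    """NJ starting tree + branch-length optimization (+ NNI search)."""
    start = nj(build_matrix(ds, "k2p"))
    engine = PatternLikelihood.from_dataset(ds)
    tree = start.copy()
    if do_nni and len(ds) >= 4:
        tree, lnl = engine.nni_search(tree, model, tol=tol)
    else:
        lnl = engine.optimize_branches(tree, model, tol=tol)
    return LikelihoodResult(lnl, tree, model, model.n_free_parameters(len(ds)))


def model_parameters_fit(
    tree: PhyloTree,
    ds: Dataset,
    model_name: str,
    gamma: bool = True,
    tol: float = 1e-3,
    max_sweeps: int = 4,
) -> SubstitutionModel:
    """Fit a named model's free parameters on a fixed tree.

    Base frequencies are empirical; exchangeabilities and the gamma shape are
    fitted by bounded coordinate-wise scalar optimization of the
    log-likelihood. Data with no variable patterns leave the gamma shape
    unidentifiable; it is then reported and fixed at the default.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    engine = PatternLikelihood.from_dataset(ds)
    freqs = _FLAT.copy() if model_name in ("JC", "K2P") else empirical_base_freqs(ds)

    X = ds.encoded()
    variable = False
    for col in X.T:
        vals = np.unique(col[col != MISSING])
        if len(vals) > 1:
            variable = True
            break
    if gamma and not variable:
        logger.warning(
            "no variable sites: gamma shape unidentifiable, fixed at %.1f",
            DEFAULT_ALPHA,
        )

    params: dict[str, float] = {}
    if model_name in ("K2P", "HKY"):
        params["kappa"] = 4.0
    elif model_name == "TIM2":
        params.update({"r_ac": 1.0, "r_ag": 4.0, "r_ct": 4.0})
    alpha = DEFAULT_ALPHA if gamma else None
    fit_alpha = gamma and variable

    def build(p: dict[str, float], a: float | None) -> SubstitutionModel:
        if model_name == "JC":
            return SubstitutionModel.jc(a)
        if model_name == "K2P":
            return SubstitutionModel.k2p(p["kappa"], a)
        if model_name == "HKY":
            return SubstitutionModel.hky(freqs, p["kappa"], a)
        return SubstitutionModel.tim2(freqs, p["r_ac"], p["r_ag"], p["r_ct"], a)

    best = engine.lnl(tree, build(params, alpha))
    for _ in range(max_sweeps):
        start_lnl = best
        for key in sorted(params):

            def neg(logv: float, key=key) -> float:
                trial = dict(params)
                trial[key] = 10.0 ** logv
                return -engine.lnl(tree, build(trial, alpha))

            res = minimize_scalar(
                neg, bounds=(-2.0, 2.0), method="bounded",
                options={"xatol": 1e-3, "maxiter": 40},
            )
            if -res.fun > best:
                params[key] = 10.0 ** float(res.x)
                best = -float(res.fun)
        if fit_alpha:

            def neg_alpha(loga: float) -> float:
                return -engine.lnl(tree, build(params, 10.0 ** loga))

            res = minimize_scalar(
                neg_alpha, bounds=(np.log10(0.02), 2.0), method="bounded",
                options={"xatol": 1e-3, "maxiter": 40},
            )
            if -res.fun > best:
                alpha = 10.0 ** float(res.x)
                best = -float(res.fun)
        if best - start_lnl < tol:
            break
    return build(params, alpha)


def information_criteria(lr: LikelihoodResult, n_sites: int) -> dict[str, float]:
    """AIC, AICc and BIC from a fitted likelihood (n = site count)."""
    k = lr.n_free_parameters
    if k < 1:
        raise ValueError("n_free_parameters must be >= 1")
    aic = 2.0 * k - 2.0 * lr.log_likelihood
    denom = n_sites - k - 1
    aicc = aic + 2.0 * k * (k + 1) / denom if denom > 0 else float("nan")
    bic = k * np.log(n_sites) - 2.0 * lr.log_likelihood
    return {"AIC": aic, "AICc": aicc, "BIC": bic}


def compare_models(
    ds: Dataset,
    tree: PhyloTree,
    model_names: tuple[str, ...] = MODEL_NAMES,
    gamma: bool = True,
) -> dict[str, dict[str, float]]:
    """Fit each candidate model on the fixed tree and score AIC/AICc/BIC."""
    engine = PatternLikelihood.from_dataset(ds)
    out = {}
    for name in model_names:
        model = model_parameters_fit(tree, ds, name, gamma=gamma)
        lnl = engine.lnl(tree, model)
        lr = LikelihoodResult(lnl, tree, model, model.n_free_parameters(len(ds)))
        row = {"lnL": lnl, "k": float(lr.n_free_parameters)}
        row.update(information_criteria(lr, ds.alignment_length))
        label = name + ("+G4" if gamma else "")
        out[label] = row
    return out


def ml_bootstrap(
    ds: Dataset,
    model: SubstitutionModel,
    replicates: int = 100,
    seed: int = 0,
    do_nni: bool = True,
    point: LikelihoodResult | None = None,
) -> LikelihoodResult:
    """ML point tree annotated with bootstrap support.

    Each replicate resamples alignment columns, builds an NJ starting tree
    and re-optimizes under the model (with NNI when ``do_nni``); supports are
    the percentage of replicates containing each internal bipartition of the
    point-estimate ML tree.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    result = point if point is not None else ml_tree(ds, model, do_nni=do_nni)
    tree = result.tree.copy()
    targets = tree.nontrivial_splits()
    counts = {s: 0 for s in targets}

    X = ds.encoded()
    ids = ds.ids
    L = X.shape[1]
    rng = np.random.default_rng(seed)
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        Xb = X[:, cols]
        dmb = matrix_from_encoded(Xb, ids, "k2p")
        if dmb.undefined:
            dropped += 1
            continue
        engine = PatternLikelihood(Xb, ids)
        rep_tree = nj(dmb)
        if do_nni and len(ids) >= 4:
            rep_tree, _ = engine.nni_search(rep_tree, model)
        else:
            engine.optimize_branches(rep_tree, model)
        rep_splits = rep_tree.nontrivial_splits()
        for s in targets:
            if s in rep_splits:
                counts[s] += 1
    used = replicates - dropped
    if dropped > 0.05 * replicates:
        logger.warning("%d of %d ML bootstrap replicates dropped", dropped, replicates)
    if used == 0:
        raise TreeError("every ML bootstrap replicate had undefined pairs")
    tree.support = {s: 100.0 * c / used for s, c in counts.items()}
    return LikelihoodResult(result.log_likelihood, tree, model, result.n_free_parameters)
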