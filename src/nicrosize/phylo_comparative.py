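"""Continuous-trait comparative methods on dated trees.

Everything here assumes a Brownian-motion (BM) model of trait evolution: tip
values are jointly multivariate normal with covariance sigma^2 * C, where
C[i, j] is the shared path length (depth of the MRCA) of tips i and j.

* :func:`pic` — Felsenstein's phylogenetically independent contrasts by
  pruning, with branch-length augmentation passed rootward.
* :func:`ancestral_states` — ML/GLS ancestral states with 95% CIs, plus
  per-edge linear interpolation for export.
* :func:`bm_loglik` / :func:`pagel_lambda` — profile log-likelihood under the
  lambda-transformed covariance (off-diagonals scaled by lambda) and its ML
  estimate with a likelihood-ratio test against lambda = 0.
* :func:`blomberg_k` — Blomberg's K with the phylogenetically corrected mean
  and a tip-label permutation test on the variance of contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_io import DatedTree

__all__ = [
    "Contrast",
    "ContrastSet",
    "AncestralStates",
    "SignalResult",
    "pic",
    "contrast_matrix",
    "ancestral_states",
    "edge_interpolated_states",
    "bm_loglik",
    "pagel_lambda",
    "lambda_upper_bound",
    "blomberg_k",
]


@dataclass(frozen=True)
class Contrast:
    node_id: str
    contrast: float  # standardized: (x_i - x_j) / sqrt(v_i + v_j)
    variance: float  # expected variance v_i + v_j (Ma)


@dataclass(frozen=True)
class ContrastSet:
    contrasts: list[Contrast]
    root_state: float  # pruning estimate of the root value (= GLS mean)
    root_variance: float  # augmented branch-length variance at the root

    def values(self) -> np.ndarray:
        return np.array([c.contrast for c in self.contrasts])

    def variances(self) -> np.ndarray:
        return np.array([c.variance for c in self.contrasts])


@dataclass(frozen=True)
class AncestralStates:
    node_states: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    sigma2: float  # ML Brownian rate (mm^2 / Ma)


@dataclass(frozen=True)
class SignalResult:
    """Phylogenetic-signal estimates; lambda fields, K fields, or both."""

    lambda_hat: float | None = None
    loglik: float | None = None
    lrt_p: float | None = None
    K: float | None = None
    K_p: float | None = None
    n_perm: int | None = None


def _check_tips(tree: DatedTree, tip_values: Mapping[str, float]) -> dict[str, float]:
    missing = [t for t in tree.tip_names if t not in tip_values]
    if missing:
        raise ValueError(f"tip values missing for: {missing}")
    extra = sorted(set(tip_values) - set(tree.tip_names))
    if extra:
        warnings.warn(f"values for taxa absent from the tree ignored: {extra}", stacklevel=3)
    return {t: float(tip_values[t]) for t in tree.tip_names}


def _prune(tree: DatedTree, values: Mapping[str, np.ndarray | float]):
    """Felsenstein pruning over (possibly vector-valued) tip states.

    Returns (contrast rows, root state, root variance). With vector-valued
    tips the contrast entries are linear-coefficient vectors, which is how
    :func:`contrast_matrix` extracts the linear operator.
    """
    state: dict = {}
    extra: dict = {}
    rows = []
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            state[node] = values[node.taxon.label]
            extra[node] = 0.0
            continue
        a, b = node.child_nodes()
        va = (a.edge.length or 0.0) + extra[a]
        vb = (b.edge.length or 0.0) + extra[b]
        rows.append((node.label, (state[a] - state[b]) / np.sqrt(va + vb), va + vb))
        state[node] = (vb * state[a] + va * state[b]) / (va + vb)
        extra[node] = va * vb / (va + vb)
    root = tree.tree.seed_node
    return rows, state[root], extra[root]


def pic(tree: DatedTree, tip_values: Mapping[str, float]) -> ContrastSet:
    """Standardized independent contrasts, one per internal node."""
    vals = _check_tips(tree, tip_values)
    rows, root_state, root_var = _prune(tree, vals)
    contrasts = [Contrast(node_id=nid, contrast=float(c), variance=float(v))
                 for nid, c, v in rows]
    return ContrastSet(contrasts=contrasts, root_state=float(root_state),
                       root_variance=float(root_var))


def contrast_matrix(tree: DatedTree) -> tuple[list[str], np.ndarray]:
    """Linear operator W with contrasts = W @ x for tips in ``tip_names`` order."""
    basis = {name: np.eye(tree.n_tips)[i] for i, name in enumerate(tree.tip_names)}
    rows, _, _ = _prune(tree, basis)
    return [nid for nid, _, _ in rows], np.array([c for _, c, _ in rows])


# ---------------------------------------------------------------------------
# Ancestral states (GLS under BM)


def _gls_pieces(tree: DatedTree, x: np.ndarray):
    _, C = tree.vcv()
    Cinv = np.linalg.inv(C)
    one = np.ones(len(x))
    denom = one @ Cinv @ one
    mu = (one @ Cinv @ x) / denom
    resid = x - mu
    quad = resid @ Cinv @ resid
    return C, Cinv, one, denom, mu, resid, quad


def ancestral_states(tree: DatedTree, tip_values: Mapping[str, float]) -> AncestralStates:
    """ML ancestral states under BM with 95% CIs.

    The state at internal node a is the GLS/kriging predictor
    mu + c' C^{-1} (x - mu 1) with c[i] the shared path length between node a
    and tip i; its variance includes the uncertainty of the estimated root
    mean. The BM rate is the ML estimate (residual quadratic form / n).
    """
    vals = _check_tips(tree, tip_values)
    x = np.array([vals[t] for t in tree.tip_names])
    n = len(x)
    C, Cinv, one, denom, mu, resid, quad = _gls_pieces(tree, x)
    sigma2 = quad / n
    order = {name: i for i, name in enumerate(tree.tip_names)}

    # shared path length between an internal node and each tip: depth of the
    # deepest ancestor of the node (itself included) on the tip's root path
    leafsets: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = {order[node.taxon.label]}
        else:
            s = set()
            for ch in node.child_nodes():
                s |= leafsets[ch]
            leafsets[node] = s

    states: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    for node in tree.internal_nodes():
        c = np.empty(n)
        inside = leafsets[node]
        c[list(inside)] = tree.depth(node)
        anc = node.parent_node
        prev = inside
        while anc is not None:
            here = leafsets[anc] - prev
            if here:
                c[list(here)] = tree.depth(anc)
            prev = leafsets[anc]
            anc = anc.parent_node
        w = Cinv @ c
        a_hat = mu + w @ resid
        pred_var = sigma2 * (tree.depth(node) - c @ w + (1.0 - one @ w) ** 2 / denom)
        pred_var = max(pred_var, 0.0)
        half = 1.959963984540054 * np.sqrt(pred_var)
        states[node.label] = float(a_hat)
        ci[node.label] = (float(a_hat - half), float(a_hat + half))
    return AncestralStates(node_states=states, ci95=ci, sigma2=float(sigma2))


def edge_interpolated_states(
    tree: DatedTree,
    states: AncestralStates,
    tip_values: Mapping[str, float],
    n_points: int = 10,
) -> pd.DataFrame:
    """Linear interpolation of states along every edge (for map/contour export)."""
    rows = []
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        v0 = states.node_states[parent.label]
        v1 = (tip_values[node.taxon.label] if node.is_leaf()
              else states.node_states[node.label])
        child_id = node.taxon.label if node.is_leaf() else node.label
        for f in np.linspace(0.0, 1.0, n_points):
            rows.append({
                "parent": parent.label, "child": child_id, "fraction": float(f),
                "age_ma": tree.age(parent) - f * (node.edge.length or 0.0),
                "state_mm": v0 + f * (v1 - v0),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pagel's lambda


def _lambda_cov(C: np.ndarray, lambda_: float) -> np.ndarray:
    V = lambda_ * C
    np.fill_diagonal(V, np.diag(C))
    return V


def lambda_upper_bound(tree: DatedTree) -> float:
    """Largest lambda keeping the transformed covariance positive definite.

    For an ultrametric tree this is root height divided by the depth of the
    internal node closest to the tips.
    """
    depths = [tree.depth(nd) for nd in tree.internal_nodes()]
    d_max = max(depths)
    if d_max <= 0:
        return np.inf
    _, C = tree.vcv()
    return float(np.min(np.diag(C)) / d_max)


def bm_loglik(tree: DatedTree, tip_values: Mapping[str, float], lambda_: float = 1.0) -> float:
    """Profile BM log-likelihood on the lambda-transformed tree.

    The root state and rate are profiled out at their ML values; only lambda
    remains. Raises if the transformed covariance is not positive definite.
    """
    vals = _check_tips(tree, tip_values)
    x = np.array([vals[t] for t in tree.tip_names])
    n = len(x)
    _, C = tree.vcv()
    V = _lambda_cov(C, lambda_)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        raise ValueError(f"lambda-transformed covariance not positive definite at lambda={lambda_}")
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Li = np.linalg.inv(L)
    Vinv = Li.T @ Li
    one = np.ones(n)
    mu = (one @ Vinv @ x) / (one @ Vinv @ one)
    resid = x - mu
    sigma2 = (resid @ Vinv @ resid) / n
    if sigma2 <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def pagel_lambda(tree: DatedTree, tip_values: Mapping[str, float]) -> SignalResult:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs lambda=0."""
    if tree.n_tips < 10:
        warnings.warn(f"lambda estimated on only {tree.n_tips} tips", stacklevel=2)
    ub = min(lambda_upper_bound(tree), 10.0) - 1e-7
    f = lambda lam: -bm_loglik(tree, tip_values, lam)
    res = optimize.minimize_scalar(f, bounds=(0.0, ub), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"lambda optimization failed on [0, {ub}]: {res.message}")
    # bounded Brent can miss a boundary optimum; check the endpoints too
    cand = [(res.x, -res.fun), (0.0, bm_loglik(tree, tip_values, 0.0)),
            (ub, bm_loglik(tree, tip_values, ub))]
    lam_hat, ll_hat = max(cand, key=lambda t: t[1])
    ll0 = bm_loglik(tree, tip_values, 0.0)
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    return SignalResult(lambda_hat=float(lam_hat), loglik=float(ll_hat), lrt_p=p)


# ---------------------------------------------------------------------------
# Blomberg's K


def blomberg_k(
    tree: DatedTree,
    tip_values: Mapping[str, float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> SignalResult:
    """Blomberg's K with a tip-shuffling permutation test.

    K = (MSE0/MSE)_observed / E[MSE0/MSE]_BM, with the mean taken as the
    phylogenetically corrected (GLS) mean. The permutation p-value uses the
    variance of independent contrasts as the test statistic — lower variance
    means stronger signal — with the add-one estimator
    p = (1 + #{perm <= obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; permutation p will be coarse", stacklevel=2)
    vals = _check_tips(tree, tip_values)
    x = np.array([vals[t] for t in tree.tip_names])
    n = len(x)
    C, Cinv, one, denom, mu, resid, quad = _gls_pieces(tree, x)
    mse0 = resid @ resid / (n - 1)
    mse = quad / (n - 1)
    expected = (np.trace(C) - n / denom) / (n - 1)
    K = (mse0 / mse) / expected

    _, W = contrast_matrix(tree)
    obs_var = np.var(W @ x, ddof=1)
    rng = np.random.default_rng(seed)
    count = 0
    # permute tip labels in blocks to keep memory flat
    block = 2000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.array([rng.permutation(x) for _ in range(b)])
        pv = np.var(W @ perms.T, axis=0, ddof=1)
        count += int(np.sum(pv <= obs_var))
        done += b
    p = (1 + count) / (n_perm + 1)
    return SignalResult(K=float(K), K_p=float(p), n_perm=n_perm)
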