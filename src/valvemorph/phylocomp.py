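"""Phylogenetic comparative statistics.

Shared ancestry makes species non-independent: under Brownian motion (BM) a
trait's expected covariance between two tips equals the depth of their most
recent common ancestor.  This module builds that phylogenetic
variance–covariance matrix from a time-calibrated tree and uses it for

* **phylogenetic signal** — Blomberg's K (ratio of observed to BM-expected
  mean squared error, 1 under BM) with a tip-shuffling permutation test,
  and Pagel's lambda (ML multiplier on the off-diagonal covariances, 0 =
  star phylogeny, 1 = full BM structure) with a likelihood-ratio test;
* **phylogenetic GLS linear models** with sequential (type-I) sums of
  squares and a residual-randomization permutation procedure (RRPP):
  for each model term, the residuals of the reduced model containing all
  preceding terms are permuted across observations to build the null
  distribution of the term's F statistic.  Effect size Z is the standard
  deviate of log F within that distribution;
* plain Pearson correlations between morphological variables.

Trees are handled as :class:`dendropy.Tree` objects; Newick and NEXUS files
are both accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "load_tree",
    "tip_labels",
    "phylo_vcv",
    "blomberg_K",
    "pagel_lambda",
    "pgls_rrpp",
    "pearson_r",
    "pearson_matrix",
    "AnovaTable",
    "KResult",
    "LambdaResult",
    "AliasedTermError",
    "TaxonMismatchError",
    "UndefinedSignalError",
]

#: Eigenvalue floor (relative to the largest eigenvalue) used when taking
#: the inverse square root of a phylogenetic covariance; near-ultrametric
#: trees give ill-conditioned matrices.
EIG_FLOOR = 1e-10


class AliasedTermError(ValueError):
    """A model term adds no estimable dimension (perfectly confounded)."""


class TaxonMismatchError(ValueError):
    """Trait taxa and tree tips do not match; carries the offending labels."""


class UndefinedSignalError(ValueError):
    """Phylogenetic signal is undefined (constant trait)."""


# ---------------------------------------------------------------------------
# trees and covariance


def load_tree(path) -> dendropy.Tree:
    """Read a rooted tree with branch lengths from Newick or NEXUS."""
    last_error = None
    for schema in ("newick", "nexus"):
        try:
            tree = dendropy.Tree.get(path=str(path), schema=schema,
                                     preserve_underscores=True)
            break
        except Exception as exc:  # noqa: BLE001 - try the next schema
            last_error = exc
    else:
        raise ValueError(f"could not parse tree from {path!s}: {last_error}")
    return tree


def tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def phylo_vcv(tree: dendropy.Tree, lam: float = 1.0,
              taxa: "list | None" = None) -> "tuple[np.ndarray, list]":
    """Phylogenetic variance–covariance matrix from a tree.

    Entry ``(i, j)`` is the root-to-MRCA path length of tips *i* and *j*
    (the shared evolutionary history); the diagonal holds root-to-tip
    distances.  Off-diagonal entries are multiplied by ``lam`` (Pagel's
    lambda transform): ``lam = 0`` gives a diagonal (star) matrix, ``lam =
    1`` the untransformed matrix.

    Returns ``(C, labels)`` with rows ordered by ``taxa`` if given, else by
    the tree's leaf order.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("tree tip labels are not unique")
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)

    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        edge = node.edge.length or 0.0
        if edge < 0:
            raise ValueError("tree has a negative branch length")
        depth[node] = depth[node.parent_node] + edge

    C = np.zeros((n, n))
    tips_below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            tips_below[node] = [i]
            C[i, i] = depth[node]
            continue
        child_sets = [tips_below.pop(ch) for ch in node.child_nodes()]
        # each tip pair's MRCA assigns its entry exactly once
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia = np.asarray(child_sets[a])
                ib = np.asarray(child_sets[b])
                C[np.ix_(ia, ib)] = depth[node]
                C[np.ix_(ib, ia)] = depth[node]
        tips_below[node] = [i for s in child_sets for i in s]

    if taxa is not None:
        missing = sorted(set(taxa) - set(labels))
        if missing:
            raise TaxonMismatchError(
                f"taxa absent from the tree: {', '.join(missing)}")
        order = [labels.index(t) for t in taxa]
        C = C[np.ix_(order, order)]
        labels = list(taxa)

    if lam != 1.0:
        diag = np.diag(C).copy()
        C = C * lam
        np.fill_diagonal(C, diag)
    return C, labels


def align_trait(values, value_taxa, tree) -> "tuple[np.ndarray, np.ndarray, list]":
    """Align a taxon-keyed trait vector with a tree; hard error on mismatch."""
    labels = tip_labels(tree)
    value_taxa = list(value_taxa)
    extra = sorted(set(value_taxa) - set(labels))
    missing = sorted(set(labels) - set(value_taxa))
    if extra or missing:
        raise TaxonMismatchError(
            f"trait/tree mismatch; not in tree: {extra or 'none'}; "
            f"no trait value: {missing or 'none'}")
    order = [value_taxa.index(t) for t in labels]
    C, _ = phylo_vcv(tree)
    return np.asarray(values, float)[order], C, labels


def inv_sqrt_psd(C: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root with a relative eigenvalue floor."""
    w, U = np.linalg.eigh(C)
    w = np.maximum(w, EIG_FLOOR * w.max())
    return (U / np.sqrt(w)) @ U.T


# ---------------------------------------------------------------------------
# phylogenetic signal


@dataclass(frozen=True)
class KResult:
    K: float
    p: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class LambdaResult:
    lambda_hat: float
    lambda_max: float
    loglik: float
    loglik_zero: float
    lr_stat: float
    p: float
    perm_p: "float | None" = None


def _k_statistic(x: np.ndarray, Cinv: np.ndarray, expected_ratio: float,
                 ones_Cinv: np.ndarray, denom: float) -> float:
    n = len(x)
    ahat = float(ones_Cinv @ x) / denom
    dev = x - ahat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ Cinv @ dev) / (n - 1)
    return (mse0 / mse) / expected_ratio


def blomberg_K(trait, tree=None, C=None, n_perm: int = 999,
               seed: int = 0) -> KResult:
    """Blomberg's K with a tip-shuffling permutation test.

    K compares the observed mean squared error of tip values around the
    phylogenetic (GLS) mean with the MSE standardized by the phylogenetic
    covariance, scaled so that traits evolving by Brownian motion on the
    given tree have expectation 1.  K >> 1 means relatives resemble each
    other more than BM predicts; K near 0 means no phylogenetic signal.
    The p-value is the fraction of tip permutations with K at least the
    observed value, computed as ``(count + 1) / (n_perm + 1)``.
    """
    x = np.asarray(trait, float)
    if C is None:
        C, _ = phylo_vcv(tree)
    n = len(x)
    if x.std() == 0:
        raise UndefinedSignalError("trait is constant across tips")
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    ones_Cinv = ones @ Cinv
    denom = float(ones_Cinv @ ones)
    expected_ratio = (np.trace(C) - n / denom) / (n - 1)

    k_obs = _k_statistic(x, Cinv, expected_ratio, ones_Cinv, denom)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        k_perm = _k_statistic(rng.permutation(x), Cinv, expected_ratio,
                              ones_Cinv, denom)
        if k_perm >= k_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return KResult(K=float(k_obs), p=float(p), n_perm=n_perm, seed=seed)


def _gls_loglik(x: np.ndarray, C: np.ndarray) -> float:
    """Profile log-likelihood of a BM-style multivariate normal: the mean
    and scale sigma^2 are profiled out analytically."""
    n = len(x)
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    ahat = float(ones @ Cinv @ x) / float(ones @ Cinv @ ones)
    dev = x - ahat
    sig2 = float(dev @ Cinv @ dev) / n
    if sig2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sig2) + logdet + n)


def _lambda_upper_bound(C: np.ndarray, cap: float = 2.0) -> float:
    """Largest lambda (up to ``cap``) keeping the transformed matrix
    positive definite, found by bisection on a Cholesky test."""
    diag = np.diag(C).copy()

    def is_pd(lam):
        M = C * lam
        np.fill_diagonal(M, diag)
        try:
            np.linalg.cholesky(M)
            return True
        except np.linalg.LinAlgError:
            return False

    if not is_pd(1.0):
        lo, hi = 0.0, 1.0
    elif is_pd(cap):
        return cap
    else:
        lo, hi = 1.0, cap
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if is_pd(mid):
            lo = mid
        else:
            hi = mid
    return lo


def pagel_lambda(trait, tree=None, C=None) -> LambdaResult:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test.

    The off-diagonal entries of the phylogenetic covariance are scaled by
    lambda and the multivariate-normal likelihood of the tip values is
    maximized over lambda on ``[0, lambda_max]``, where ``lambda_max`` is
    the largest value keeping the matrix positive definite.  The reported
    p-value is a likelihood-ratio test against ``lambda = 0`` (no signal,
    chi-squared with 1 df).
    """
    x = np.asarray(trait, float)
    if C is None:
        C, _ = phylo_vcv(tree)
    if x.std() == 0:
        raise UndefinedSignalError("trait is constant across tips")
    diag = np.diag(C).copy()

    def transformed(lam):
        M = C * lam
        np.fill_diagonal(M, diag)
        return M

    lam_max = _lambda_upper_bound(C)

    def neg_ll(lam):
        return -_gls_loglik(x, transformed(lam))

    res = minimize_scalar(neg_ll, bounds=(0.0, lam_max), method="bounded",
                          options={"xatol": 1e-6})
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    # the bounded optimizer never evaluates exactly at the ends; check them
    for endpoint in (0.0, lam_max):
        ll_end = _gls_loglik(x, transformed(endpoint))
        if ll_end > ll_hat:
            lam_hat, ll_hat = endpoint, ll_end
    ll0 = _gls_loglik(x, transformed(0.0))
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return LambdaResult(lambda_hat=lam_hat, lambda_max=float(lam_max),
                        loglik=ll_hat, loglik_zero=ll0, lr_stat=lr, p=p)


# ---------------------------------------------------------------------------
# GLS linear models with RRPP ANOVA


@dataclass(frozen=True)
class AnovaTable:
    """Sequential (type-I) ANOVA table with permutation inference.

    ``table`` has one row per model term plus ``Residuals`` and ``Total``,
    with columns Df, SS, MS, Rsq, F, Z and ``Pr(>F)``.
    """

    table: pd.DataFrame
    n_perm: int
    seed: int
    formula: str = ""

    def __getitem__(self, term):
        return self.table.loc[term]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="term")


def _term_blocks(terms, data: pd.DataFrame):
    """Expand ordered term names into design-matrix blocks.

    Categorical (object / category / bool) columns become treatment-coded
    dummies (first level dropped); numeric columns enter as-is.
    """
    blocks = []
    for term in terms:
        col = data[term]
        if (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
                or col.dtype == bool):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            blocks.append((term, dummies.to_numpy()))
        else:
            blocks.append((term, col.to_numpy(dtype=float)[:, None]))
    return blocks


def _hat(X: np.ndarray):
    """Orthogonal-projection (hat) matrix and rank of a design matrix."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    keep = diag > max(X.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    Q = Q[:, keep]
    return Q @ Q.T, int(keep.sum())


def pgls_rrpp(response, terms, data: pd.DataFrame, cov=None,
              n_perm: int = 999, seed: int = 0) -> AnovaTable:
    """Phylogenetic GLS linear model with RRPP permutation ANOVA.

    Parameters
    ----------
    response : str
        Column of ``data`` holding the response variable.
    terms : sequence of str
        Ordered model terms (columns of ``data``); sums of squares are
        sequential in this order.
    data : DataFrame
        One row per tip, aligned with ``cov`` if given.
    cov : (n, n) array, optional
        Phylogenetic covariance; identity (ordinary ANOVA) if omitted.
        GLS is performed by premultiplying response and design by the
        inverse square root of this matrix.
    n_perm : int
        Random permutations of reduced-model residuals; the observed
        arrangement is included in the null distribution, so the smallest
        attainable p is ``1 / (n_perm + 1)``.

    Residual randomization: for each term the residuals of the model with
    all preceding terms are permuted and added back to that reduced model's
    fitted values, and the term's F statistic recomputed; p is the upper
    tail probability, Z the standard deviate of log F.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm = {n_perm} is very small; p-values will be "
                      "coarse", stacklevel=2)
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    E = inv_sqrt_psd(np.asarray(cov, float)) if cov is not None else None
    yt = E @ y if E is not None else y

    ones = np.ones((n, 1))
    blocks = _term_blocks(terms, data)
    X = ones
    if E is not None:
        X = E @ X
    H_prev, rank_prev = _hat(X)
    hats = [(H_prev, rank_prev)]
    for name, block in blocks:
        Xb = E @ block if E is not None else block
        X = np.hstack([X, Xb])
        H, rank = _hat(X)
        if rank == hats[-1][1]:
            raise AliasedTermError(
                f"term {name!r} adds no estimable dimension (aliased)")
        hats.append((H, rank))

    H0 = hats[0][0]
    H_full, rank_full = hats[-1]
    df_res = n - rank_full
    if df_res <= 0:
        raise AliasedTermError("model is saturated; no residual df")
    I = np.eye(n)
    R_full = I - H_full
    ss_total = float(yt @ (I - H0) @ yt)
    df_total = n - 1

    rng = np.random.default_rng(seed)
    perm_idx = np.vstack([np.arange(n)] +
                         [rng.permutation(n) for _ in range(n_perm)])

    rows = []
    for k, (name, _) in enumerate(blocks):
        H_red, rank_red = hats[k]
        H_cur, rank_cur = hats[k + 1]
        df_k = rank_cur - rank_red
        D = H_cur - H_red
        fitted = H_red @ yt
        resid = yt - fitted
        Yp = fitted[None, :] + resid[perm_idx]          # (n_perm+1, n)
        # projection quadratic forms are non-negative; clamp float noise
        ss_k = np.maximum(np.einsum("pi,ij,pj->p", Yp, D, Yp), 0.0)
        rss = np.maximum(np.einsum("pi,ij,pj->p", Yp, R_full, Yp), 0.0)
        # a saturated model has zero residual SS and an infinite F
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_k / df_k) / (rss / df_res)
        F = np.where(np.isnan(F), np.inf, F)
        p = float(np.mean(F >= F[0]))
        logF = np.log(np.maximum(F, 1e-300))
        finite = logF[np.isfinite(logF)]
        sd = finite.std(ddof=1) if len(finite) > 1 else 0.0
        Z = float((logF[0] - finite.mean()) / sd) if sd > 0 else 0.0
        rows.append({"term": name, "Df": df_k, "SS": float(ss_k[0]),
                     "MS": float(ss_k[0]) / df_k,
                     "Rsq": float(ss_k[0]) / ss_total,
                     "F": float(F[0]), "Z": Z, "Pr(>F)": p})

    ss_res = max(float(yt @ R_full @ yt), 0.0)
    rows.append({"term": "Residuals", "Df": df_res, "SS": ss_res,
                 "MS": ss_res / df_res, "Rsq": ss_res / ss_total,
                 "F": np.nan, "Z": np.nan, "Pr(>F)": np.nan})
    rows.append({"term": "Total", "Df": df_total, "SS": ss_total,
                 "MS": np.nan, "Rsq": np.nan, "F": np.nan, "Z": np.nan,
                 "Pr(>F)": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    formula = f"{response} ~ {' + '.join(terms)}"
    return AnovaTable(table=table, n_perm=n_perm, seed=seed, formula=formula)


# ---------------------------------------------------------------------------
# correlations


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on short or constant input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def pearson_matrix(data: pd.DataFrame, variables) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix for the given columns."""
    variables = list(variables)
    out = pd.DataFrame(np.eye(len(variables)), index=variables,
                       columns=variables)
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            r = pearson_r(data[a], data[b])
            out.loc[a, b] = out.loc[b, a] = r
    return out
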