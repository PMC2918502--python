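"""Pagel's lambda phylogenetic signal by maximum likelihood.

Lambda multiplies the off-diagonal elements of the phylogenetic covariance
matrix C (entry (i, j) = shared root-to-tip path length of tips i and j):
lambda = 0 means tip values are independent of phylogeny, lambda = 1 means
Brownian motion on the given tree.  The mean is profiled out by GLS and the
scale by its ML estimator (divisor n), leaving a one-dimensional likelihood
maximised on [0, 1]; likelihood-ratio tests against lambda = 0 and 1 use a
chi-square reference with 1 df.

Because the true branch lengths of the avian supertree are contentious, two
branch-length hypotheses are supported besides the tree as given: ``equal``
(every branch length 1) and ``proportional`` (node heights proportional to
the number of descendant tips minus one, yielding an ultrametric tree of
unit depth).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import linalg, optimize, stats


class PhyloError(ValueError):
    pass


@dataclass
class Phylo:
    """A rooted tree with branch lengths and a branch-length-scheme tag."""

    tree: dendropy.Tree
    scheme: str = "as-given"

    @property
    def tip_labels(self) -> list[str]:
        return sorted(t.label for t in self.tree.taxon_namespace)

    @property
    def n_tips(self) -> int:
        return len(self.tree.taxon_namespace)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class LambdaFit:
    """ML estimate of lambda with LR tests against the 0 and 1 endpoints."""

    lambda_hat: float
    lnL_hat: float
    lnL_1: float
    lnL_0: float
    LR_1: float
    LR_0: float
    p_1: float
    p_0: float
    mu_hat: float
    sigma2_hat: float
    scheme: str
    at_bound: bool


def read_newick_tree(path_or_string, scheme: str = "as-given") -> Phylo:
    """Load a rooted Newick tree (file path or literal string)."""
    src = str(path_or_string)
    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, **kwargs)
        else:
            tree = dendropy.Tree.get(path=src, **kwargs)
    except Exception as exc:  # dendropy raises several parse error types
        raise PhyloError(f"could not parse Newick input: {exc}") from exc
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise PhyloError(f"duplicate tip label(s): {dupes}")
    return Phylo(tree=tree, scheme=scheme)


def write_newick_tree(phylo: Phylo, path) -> None:
    with open(path, "w") as fh:
        fh.write(phylo.as_newick() + "\n")


def apply_branch_scheme(phylo: Phylo, scheme: str) -> Phylo:
    """Return a tree under the requested branch-length hypothesis.

    equal: every branch length 1.  proportional: node height above the tips
    proportional to (descendant tips - 1), scaled so the (ultrametric) tree
    has unit depth.  as-given: unchanged.
    """
    if scheme == "as-given":
        return Phylo(tree=phylo.tree.clone(depth=1), scheme=scheme)
    tree = phylo.tree.clone(depth=1)
    if scheme == "equal":
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                edge.length = 1.0
    elif scheme == "proportional":
        n = len(tree.taxon_namespace)
        if n < 2:
            raise PhyloError("proportional scheme needs >= 2 tips")
        for node in tree.postorder_node_iter():
            k = sum(1 for _ in node.leaf_iter())
            node._height = (k - 1) / (n - 1)
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            node.edge.length = node.parent_node._height - node._height
    else:
        raise PhyloError(f"unknown branch-length scheme: {scheme!r}")
    return Phylo(tree=tree, scheme=scheme)


def phylo_covariance(phylo: Phylo) -> tuple[np.ndarray, list[str]]:
    """Tip covariance matrix: entry (i, j) = root depth of the MRCA of i, j.

    Returns the matrix and its (sorted) tip-label order.
    """
    tree = phylo.tree
    labels = phylo.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node._depth = 0.0
        else:
            length = node.edge.length if node.edge.length is not None else 0.0
            node._depth = node.parent_node._depth + length
    C = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            node._tipset = [i]
            C[i, i] = node._depth
        else:
            children = [c._tipset for c in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia = np.asarray(children[a])
                    ib = np.asarray(children[b])
                    C[np.ix_(ia, ib)] = node._depth
                    C[np.ix_(ib, ia)] = node._depth
            node._tipset = [i for ts in children for i in ts]
    return C, labels


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = C * lam
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def lambda_loglik(y: np.ndarray, C: np.ndarray, lam: float) -> float:
    """Profiled MVN log-likelihood at a given lambda.

    The mean is the GLS estimate and the scale the ML (divisor n) estimate
    under C_lambda; evaluation goes through a Cholesky factorisation.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if C.shape != (n, n):
        raise PhyloError("trait vector and covariance matrix sizes differ")
    if not np.all(np.isfinite(y)):
        raise PhyloError("trait values must be finite")
    Cl = _lambda_cov(C, lam)
    try:
        cho = linalg.cho_factor(Cl, lower=True)
    except linalg.LinAlgError as exc:
        raise PhyloError(f"C_lambda singular at lambda={lam}: {exc}") from exc
    one = np.ones(n)
    Ci_y = linalg.cho_solve(cho, y)
    Ci_1 = linalg.cho_solve(cho, one)
    mu = float(one @ Ci_y) / float(one @ Ci_1)
    r = y - mu
    q = float(r @ linalg.cho_solve(cho, r))
    if q <= 0:
        raise PhyloError("degenerate (constant) trait vector")
    sigma2 = q / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def _profile_mu_sigma(y: np.ndarray, Cl: np.ndarray) -> tuple[float, float]:
    cho = linalg.cho_factor(Cl, lower=True)
    one = np.ones(len(y))
    mu = float(one @ linalg.cho_solve(cho, y)) / float(
        one @ linalg.cho_solve(cho, one)
    )
    r = y - mu
    return mu, float(r @ linalg.cho_solve(cho, r)) / len(y)


def fit_lambda(
    y: np.ndarray,
    phylo: Phylo | None = None,
    scheme: str | None = None,
    *,
    C: np.ndarray | None = None,
    tip_order: list[str] | None = None,
    tol: float = 1e-6,
) -> LambdaFit:
    """Bounded ML search for lambda on [0, 1] with LR tests at the endpoints.

    ``y`` may be a plain vector ordered like ``tip_order`` (or the sorted tip
    labels of the tree), or a dict keyed by tip label.
    """
    if C is None:
        if phylo is None:
            raise PhyloError("need either a tree or a covariance matrix")
        if scheme is not None and scheme != phylo.scheme:
            phylo = apply_branch_scheme(phylo, scheme)
        C, tip_order = phylo_covariance(phylo)
    scheme_tag = scheme or (phylo.scheme if phylo is not None else "as-given")
    if isinstance(y, dict):
        if tip_order is None:
            raise PhyloError("tip order unknown; cannot align trait dict")
        y = np.array([y[t] for t in tip_order], dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        raise PhyloError("need at least 4 tips to fit lambda")

    def nll(lam: float) -> float:
        return -lambda_loglik(y, C, lam)

    # the profile likelihood can be multimodal on small trees: bracket the
    # best point of a coarse scan, then refine with a bounded search
    coarse = np.linspace(0.0, 1.0, 41)
    coarse_ll = np.array([-nll(l) for l in coarse])
    i = int(np.argmax(coarse_ll))
    lo, hi = coarse[max(i - 1, 0)], coarse[min(i + 1, len(coarse) - 1)]
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    if not res.success:
        raise PhyloError(f"lambda optimiser failed: {res.message}")
    lnL_0 = coarse_ll[0]
    lnL_1 = coarse_ll[-1]
    # the bounded search cannot land exactly on an endpoint; take the best
    candidates = [(float(res.x), -float(res.fun)), (0.0, lnL_0), (1.0, lnL_1)]
    lambda_hat, lnL_hat = max(candidates, key=lambda c: c[1])
    mu_hat, sigma2_hat = _profile_mu_sigma(y, _lambda_cov(C, lambda_hat))
    LR_1 = max(2.0 * (lnL_hat - lnL_1), 0.0)
    LR_0 = max(2.0 * (lnL_hat - lnL_0), 0.0)
    return LambdaFit(
        lambda_hat=lambda_hat,
        lnL_hat=lnL_hat,
        lnL_1=lnL_1,
        lnL_0=lnL_0,
        LR_1=LR_1,
        LR_0=LR_0,
        p_1=float(stats.chi2.sf(LR_1, df=1)),
        p_0=float(stats.chi2.sf(LR_0, df=1)),
        mu_hat=mu_hat,
        sigma2_hat=sigma2_hat,
        scheme=scheme_tag,
        at_bound=lambda_hat in (0.0, 1.0),
    )


def lr_statistics(lnL_hat: float, lnL_1: float, lnL_0: float) -> tuple[float, float]:
    """Likelihood-ratio statistics 2*(lnL_hat - lnL_x) against lambda = 1, 0."""
    return 2.0 * (lnL_hat - lnL_1), 2.0 * (lnL_hat - lnL_0)


def fits_to_frame(fits: dict[str, LambdaFit]) -> "pd.DataFrame":
    """Lambda fits as a summary table (trait, lambda, lnLs, LRs, ps, scheme)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "trait": name,
                "lambda": f.lambda_hat,
                "lnL_lambda": f.lnL_hat,
                "lnL1": f.lnL_1,
                "lnL0": f.lnL_0,
                "LR1": f.LR_1,
                "LR0": f.LR_0,
                "p1": f.p_1,
                "p0": f.p_0,
                "scheme": f.scheme,
            }
            for name, f in fits.items()
        ]
    )
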