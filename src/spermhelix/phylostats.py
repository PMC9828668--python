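"""Phylogenetic GLS, phylogenetic linear mixed models and repeatability.

Implements the comparative machinery from first principles on top of
numpy/scipy linear algebra:

* ``phylo_covariance`` — Brownian-motion covariance C from a rooted tree
  (C[i, j] = shared root-to-MRCA path length);
* ``fit_pgls`` — generalized least squares with Pagel's lambda profiled by
  maximum likelihood (lambda multiplies the off-diagonal of C);
* ``fit_phylo_lmm`` — mixed model with a phylogenetically structured species
  random effect for repeated observations per species, variance components
  by REML, fixed-effect tests by ML likelihood ratio;
* ``repeatability`` — intraclass correlation from a random-intercept model
  with a measurement-kind fixed effect, CI by parametric bootstrap.

The mixed-model likelihood is evaluated with the Woodbury identity so each
step costs one m x m solve (m = number of species or points), never an
n_obs x n_obs factorization.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "PhyloCovariance",
    "ModelFit",
    "GLSResult",
    "RepeatabilityResult",
    "phylo_covariance",
    "lambda_transform",
    "gls_fit",
    "fit_pgls",
    "fit_phylo_lmm",
    "drop_nonsignificant_interaction",
    "repeatability",
]

_CHI2_95_DF1 = stats.chi2.ppf(0.95, 1)


@dataclass
class PhyloCovariance:
    """Among-species covariance implied by Brownian motion on a tree."""

    species_order: tuple[str, ...]
    matrix: np.ndarray
    height: float

    def index_of(self, species: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.species_order)}
        missing = [s for s in species if s not in pos]
        if missing:
            raise KeyError(f"species not on tree: {missing}")
        return np.array([pos[s] for s in species], dtype=int)

    def subset(self, species: Sequence[str]) -> "PhyloCovariance":
        ix = self.index_of(species)
        return PhyloCovariance(
            species_order=tuple(species),
            matrix=self.matrix[np.ix_(ix, ix)],
            height=self.height,
        )


@dataclass
class ModelFit:
    """Coefficients, intervals, variance components and diagnostics."""

    coefficients: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    lambda_: Optional[float]
    lambda_ci: Optional[tuple[float, float]]
    variance_components: dict[str, float]
    loglik: float  # ML log-likelihood (for LR tests)
    n_obs: int
    n_species: int
    p_values: dict[str, float] = field(default_factory=dict)
    transform_applied: bool = False
    method: str = ""
    reml_loglik: Optional[float] = None
    residuals: Optional[np.ndarray] = field(default=None, repr=False)
    notes: dict = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)


@dataclass
class GLSResult:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    sigma2_ml: float
    sigma2: float  # unbiased, rss/(n-p)
    reml_loglik: float
    cov_beta: np.ndarray
    residuals: np.ndarray
    n_obs: int


def phylo_covariance(tree) -> PhyloCovariance:
    """Shared-path covariance matrix from a rooted dendropy tree.

    C[i, j] = depth of MRCA(i, j) measured from the root; C[i, i] = tip depth
    (equal to tree height for an ultrametric tree).
    """
    tips = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    if len(tips) < 3:
        raise ValueError("tree must have at least 3 tips")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
    labels = [t.taxon.label for t in tips]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    # depth of every node from the root
    depth: dict = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    n = len(tips)
    pos = {t.taxon.label: i for i, t in enumerate(tips)}
    C = np.zeros((n, n))
    for i, t in enumerate(tips):
        C[i, i] = depth[t]
    # postorder accumulation of tip sets; MRCA depth fills the off-diagonals
    tipsets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            tipsets[nd] = [pos[nd.taxon.label]]
            continue
        children = [tipsets[c] for c in nd.child_nodes()]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        C[i, j] = C[j, i] = depth[nd]
        merged: list[int] = []
        for c in children:
            merged.extend(c)
        tipsets[nd] = merged
    height = float(np.max(np.diag(C)))
    if height <= 0:
        raise ValueError("tree has zero height")
    return PhyloCovariance(species_order=tuple(labels), matrix=C, height=height)


def lambda_transform(C: PhyloCovariance | np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonal of C multiplied by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C)
    out = lam * M
    np.fill_diagonal(out, np.diag(M))
    return out


def gls_fit(X: np.ndarray, y: np.ndarray, V: np.ndarray) -> GLSResult:
    """Exact GLS under a fixed covariance V, with sigma^2 profiled out.

    beta = (X' V^-1 X)^-1 X' V^-1 y; the Gaussian log-likelihood is reported
    at the ML estimate sigma2 = r' V^-1 r / n.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is singular")
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        # near-singular covariances (e.g. cherries splitting just below the
        # tips at lambda ~ 1) get a relative ridge before giving up
        jitter = 1e-10 * float(np.mean(np.diag(V)))
        try:
            cf = linalg.cho_factor(V + jitter * np.eye(n), lower=True)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance not positive definite: {exc}"
            )
    ViX = linalg.cho_solve(cf, X)
    Viy = linalg.cho_solve(cf, y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    r = y - X @ beta
    rVir = float(r @ linalg.cho_solve(cf, r))
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    sigma2_ml = rVir / n
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdetV + n)
    sigma2 = rVir / (n - p) if n > p else float("nan")
    if n > p:
        _, logdetXtViX = np.linalg.slogdet(XtViX)
        reml_loglik = -0.5 * (
            (n - p) * math.log(2.0 * math.pi * sigma2)
            + logdetV
            + logdetXtViX
            + (n - p)
        )
    else:
        reml_loglik = float("nan")
    cov_beta = sigma2 * np.linalg.inv(XtViX)
    return GLSResult(
        beta=beta,
        se=np.sqrt(np.diag(cov_beta)),
        loglik=loglik,
        sigma2_ml=sigma2_ml,
        sigma2=sigma2,
        reml_loglik=reml_loglik,
        cov_beta=cov_beta,
        residuals=r,
        n_obs=n,
    )


def _profile_ci(xs: np.ndarray, lls: np.ndarray, best_x: float, best_ll: float,
                lo: float, hi: float) -> tuple[float, float]:
    """Likelihood-profile CI by linear interpolation on a grid."""
    cut = best_ll - _CHI2_95_DF1 / 2.0
    lo_ci, hi_ci = lo, hi
    order = np.argsort(xs)
    xs, lls = xs[order], lls[order]
    below = lls < cut
    # lower bound: last crossing left of best_x
    for i in range(len(xs) - 1):
        if xs[i + 1] > best_x:
            break
        if below[i] and not below[i + 1]:
            t = (cut - lls[i]) / (lls[i + 1] - lls[i])
            lo_ci = xs[i] + t * (xs[i + 1] - xs[i])
    for i in range(len(xs) - 1, 0, -1):
        if xs[i - 1] < best_x:
            break
        if below[i] and not below[i - 1]:
            t = (cut - lls[i]) / (lls[i - 1] - lls[i])
            hi_ci = xs[i] - t * (xs[i] - xs[i - 1])
    if not below[0]:
        lo_ci = lo
    if not below[-1]:
        hi_ci = hi
    return (float(lo_ci), float(hi_ci))


def fit_pgls(
    X: np.ndarray,
    y: np.ndarray,
    C: PhyloCovariance | np.ndarray,
    names: Optional[Sequence[str]] = None,
    *,
    lam: Optional[float] = None,
    grid_size: int = 101,
    compute_p: bool = True,
    method: str = "reml",
) -> ModelFit:
    """Phylogenetic GLS with Pagel's lambda profiled from the likelihood.

    One observation per species.  lambda is profiled on a grid over [0, 1]
    with local refinement, using the restricted likelihood by default
    (``method="ml"`` switches to the full ML profile; REML is the variance-
    parameter default because it decisively improves CI calibration at
    comparative sample sizes).  ``lam`` fixes lambda instead of estimating
    it.  Coefficient CIs are t-based at the lambda estimate; the lambda CI
    is a chi-square(1) profile interval; per-coefficient p-values are ML
    likelihood-ratio tests with lambda re-optimized under the null.
    """
    if method not in ("reml", "ml"):
        raise ValueError(f"unknown method {method!r}")
    Cm = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if Cm.shape != (n, n):
        raise ValueError("covariance dimension does not match data")
    if n < p + 2:
        raise ValueError(f"not identifiable: n_species={n} < p+2={p + 2}")
    if names is None:
        names = [f"b{i}" for i in range(p)]

    def ll(lam_val: float) -> float:
        res = gls_fit(X, y, lambda_transform(Cm, lam_val))
        return res.reml_loglik if method == "reml" else res.loglik

    if lam is not None:
        lam_hat = float(lam)
        lam_ci = None
        lls_grid = None
        grid = None
    else:
        grid = np.linspace(0.0, 1.0, grid_size)
        lls_grid = np.array([ll(g) for g in grid])
        i = int(np.argmax(lls_grid))  # first max -> ties break toward smaller lambda
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid_size - 1)]
        res = optimize.minimize_scalar(
            lambda v: -ll(v), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-5},
        )
        if res.success and -res.fun > lls_grid[i] + 1e-12:
            lam_hat = float(res.x)
            best_ll = float(-res.fun)
        else:
            lam_hat = float(grid[i])
            best_ll = float(lls_grid[i])
        lam_ci = _profile_ci(grid, lls_grid, lam_hat, best_ll, 0.0, 1.0)

    fit = gls_fit(X, y, lambda_transform(Cm, lam_hat))
    tcrit = stats.t.ppf(0.975, n - p)
    coefs = {nm: float(b) for nm, b in zip(names, fit.beta)}
    ses = {nm: float(s) for nm, s in zip(names, fit.se)}
    ci = {
        nm: (coefs[nm] - tcrit * ses[nm], coefs[nm] + tcrit * ses[nm])
        for nm in names
    }
    pvals: dict[str, float] = {}
    if compute_p:
        g_ml = np.linspace(0.0, 1.0, 26)
        ll_full = max(
            gls_fit(X, y, lambda_transform(Cm, g)).loglik for g in g_ml
        )
        for j, nm in enumerate(names):
            if p == 1:
                ll0 = _null_loglik(y, Cm)
            else:
                X0 = np.delete(X, j, axis=1)
                ll0 = max(
                    gls_fit(X0, y, lambda_transform(Cm, g)).loglik for g in g_ml
                )
            lr = max(0.0, 2.0 * (ll_full - ll0))
            pvals[nm] = float(stats.chi2.sf(lr, 1))
    return ModelFit(
        coefficients=coefs,
        se=ses,
        ci95=ci,
        lambda_=lam_hat,
        lambda_ci=lam_ci,
        variance_components={"sigma2": fit.sigma2, "lambda": lam_hat},
        loglik=fit.loglik,
        n_obs=n,
        n_species=n,
        p_values=pvals,
        method="PGLS-ML",
        residuals=fit.residuals,
    )


def _null_loglik(y: np.ndarray, Cm: np.ndarray) -> float:
    X0 = np.ones((len(y), 1))
    return max(
        gls_fit(X0, y, lambda_transform(Cm, g)).loglik
        for g in np.linspace(0.0, 1.0, 26)
    )


# ---------------------------------------------------------------------------
# mixed-model engine: y = X beta + Z a + e,  a ~ N(0, sa^2 A), e ~ N(0, se^2 I)
# V = se^2 (I + gamma Z A Z'),  gamma = sa^2 / se^2, profiled 1-D by REML/ML.
# ---------------------------------------------------------------------------


class _MixedWork:
    """Sufficient statistics for the Woodbury-form mixed-model likelihood."""

    def __init__(self, X: np.ndarray, y: np.ndarray, group_idx: np.ndarray,
                 A: np.ndarray):
        self.X = X
        self.y = y
        self.idx = group_idx
        self.n, self.p = X.shape
        self.m = A.shape[0]
        self.A = A
        self.counts = np.bincount(group_idx, minlength=self.m).astype(float)
        self.ZtX = np.zeros((self.m, self.p))
        np.add.at(self.ZtX, group_idx, X)
        self.Zty = np.zeros(self.m)
        np.add.at(self.Zty, group_idx, y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        jitter = 1e-10 * np.mean(np.diag(A))
        cfA = linalg.cho_factor(A + jitter * np.eye(self.m), lower=True)
        self.Ainv = linalg.cho_solve(cfA, np.eye(self.m))
        self.logdetA = 2.0 * float(np.sum(np.log(np.diag(cfA[0]))))

    def _solve(self, gamma: float):
        """Returns (beta, rWir, logdetW, XtWiX, cfM)."""
        if gamma <= 0.0:
            XtWiX = self.XtX
            beta = np.linalg.solve(XtWiX, self.Xty)
            rWir = self.yty - 2 * beta @ self.Xty + beta @ XtWiX @ beta
            return beta, max(rWir, 0.0), 0.0, XtWiX, None
        M = self.Ainv / gamma + np.diag(self.counts)
        cfM = linalg.cho_factor(M, lower=True)
        MiZtX = linalg.cho_solve(cfM, self.ZtX)
        MiZty = linalg.cho_solve(cfM, self.Zty)
        XtWiX = self.XtX - self.ZtX.T @ MiZtX
        XtWiy = self.Xty - self.ZtX.T @ MiZty
        ytWiy = self.yty - float(self.Zty @ MiZty)
        beta = np.linalg.solve(XtWiX, XtWiy)
        rWir = ytWiy - 2 * float(beta @ XtWiy) + float(beta @ XtWiX @ beta)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(cfM[0]))))
        logdetW = logdetM + self.m * math.log(gamma) + self.logdetA
        return beta, max(rWir, 0.0), logdetW, XtWiX, cfM

    def loglik(self, gamma: float, *, reml: bool) -> float:
        beta, rWir, logdetW, XtWiX, _ = self._solve(gamma)
        n, p = self.n, self.p
        if rWir <= 0.0:
            return float("inf") * -1
        if reml:
            dof = n - p
            s2 = rWir / dof
            sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
            return -0.5 * (
                dof * math.log(2 * math.pi * s2) + logdetW + logdetXtWiX + dof
            )
        s2 = rWir / n
        return -0.5 * (n * math.log(2 * math.pi * s2) + logdetW + n)

    def optimize_gamma(self, *, reml: bool) -> tuple[float, float]:
        """1-D profile over log-gamma: coarse grid then bounded refinement."""
        lngs = np.linspace(-12.0, 12.0, 25)
        cands = [0.0] + [math.exp(t) for t in lngs]
        lls = np.array([self.loglik(g, reml=reml) for g in cands])
        i = int(np.argmax(lls))
        best_g, best_ll = cands[i], float(lls[i])
        if i > 0:
            lo = math.log(cands[max(i - 1, 1)])
            hi = math.log(cands[min(i + 1, len(cands) - 1)])
            if hi > lo:
                res = optimize.minimize_scalar(
                    lambda t: -self.loglik(math.exp(t), reml=reml),
                    bounds=(lo, hi), method="bounded", options={"xatol": 1e-5},
                )
                if res.success and -res.fun > best_ll:
                    best_g, best_ll = math.exp(float(res.x)), float(-res.fun)
        if not np.isfinite(best_ll):
            raise RuntimeError("mixed-model likelihood optimization failed")
        return best_g, best_ll

    def blup(self, gamma: float) -> np.ndarray:
        """Best linear unbiased predictions of the group effects."""
        beta, _, _, _, cfM = self._solve(gamma)
        Ztr = self.Zty - self.ZtX @ beta
        if gamma <= 0.0 or cfM is None:
            return np.zeros(self.m)
        ZtWir = Ztr - self.counts * linalg.cho_solve(cfM, Ztr)
        return gamma * (self.A @ ZtWir)


def _fit_mixed(
    X: np.ndarray,
    y: np.ndarray,
    group_idx: np.ndarray,
    A: np.ndarray,
    names: Sequence[str],
    *,
    reml: bool = True,
    compute_p: bool = True,
    lambda_scale: Optional[float] = None,
) -> ModelFit:
    work = _MixedWork(X, y, group_idx, A)
    n, p = work.n, work.p
    gamma, _ = work.optimize_gamma(reml=reml)
    beta, rWir, _, XtWiX, _ = work._solve(gamma)
    dof = n - p if reml else n
    sigma2_e = rWir / dof
    sigma2_a = gamma * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(XtWiX)
    se = np.sqrt(np.diag(cov_beta))
    z = stats.norm.ppf(0.975)
    coefs = {nm: float(b) for nm, b in zip(names, beta)}
    ses = {nm: float(s) for nm, s in zip(names, se)}
    ci = {nm: (coefs[nm] - z * ses[nm], coefs[nm] + z * ses[nm]) for nm in names}

    hbar = lambda_scale if lambda_scale is not None else float(np.mean(np.diag(A)))
    denom = sigma2_a * hbar + sigma2_e
    lam = float(sigma2_a * hbar / denom) if denom > 0 else 0.0
    # profile CI for gamma -> transform monotonically to the lambda scale
    lngs = np.linspace(-12.0, 12.0, 49)
    cands = np.array([0.0] + [math.exp(t) for t in lngs])
    lls = np.array([work.loglik(g, reml=reml) for g in cands])
    g_best_ll = max(float(np.max(lls)), work.loglik(gamma, reml=reml))
    g_lo, g_hi = _profile_ci(cands, lls, gamma, g_best_ll, 0.0, float(cands[-1]))
    lam_ci = (
        float(g_lo * hbar / (g_lo * hbar + 1.0)),
        float(g_hi * hbar / (g_hi * hbar + 1.0)) if g_hi < cands[-1] else 1.0,
    )

    # loglik field always carries the ML value so LR tests are valid
    if reml:
        _, ml_ll = work.optimize_gamma(reml=False)
    else:
        ml_ll = work.loglik(gamma, reml=False)

    pvals: dict[str, float] = {}
    if compute_p:
        for j, nm in enumerate(names):
            X0 = np.delete(X, j, axis=1)
            if X0.shape[1] == 0:
                X0 = np.zeros((n, 1))
            w0 = _MixedWork(X0, y, group_idx, A)
            _, ll0 = w0.optimize_gamma(reml=False)
            lr = max(0.0, 2.0 * (ml_ll - ll0))
            pvals[nm] = float(stats.chi2.sf(lr, 1))

    a_hat = work.blup(gamma)
    resid = y - X @ beta - a_hat[group_idx]
    return ModelFit(
        coefficients=coefs,
        se=ses,
        ci95=ci,
        lambda_=lam,
        lambda_ci=lam_ci,
        variance_components={
            "phylogenetic": float(sigma2_a),
            "residual": float(sigma2_e),
            "gamma": float(gamma),
        },
        loglik=float(ml_ll),
        reml_loglik=float(work.loglik(gamma, reml=True)),
        n_obs=n,
        n_species=int(work.m),
        p_values=pvals,
        method="LMM-REML" if reml else "LMM-ML",
        residuals=resid,
    )


def fit_phylo_lmm(
    X: np.ndarray,
    y: np.ndarray,
    species_of_obs: Sequence[str],
    C: PhyloCovariance,
    names: Optional[Sequence[str]] = None,
    *,
    reml: bool = True,
    compute_p: bool = True,
) -> ModelFit:
    """Phylogenetic mixed model for repeated observations per species.

    y = X beta + a + e with a ~ N(0, sigma_a^2 C) broadcast from species to
    observations and e ~ N(0, sigma_e^2 I).  The reported lambda is the
    phylogenetic variance proportion sigma_a^2 h / (sigma_a^2 h + sigma_e^2)
    with h the mean diagonal of C.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    species = list(dict.fromkeys(species_of_obs))
    if len(species) < 3:
        raise ValueError("need at least 3 species")
    sub = C.subset(species)
    lookup = {s: i for i, s in enumerate(species)}
    idx = np.array([lookup[s] for s in species_of_obs], dtype=int)
    if names is None:
        names = [f"b{i}" for i in range(X.shape[1])]
    return _fit_mixed(
        X, y, idx, sub.matrix, names, reml=reml, compute_p=compute_p
    )


def drop_nonsignificant_interaction(
    fit_full: ModelFit, fit_reduced: ModelFit, alpha: float = 0.05
) -> tuple[ModelFit, float]:
    """ML likelihood-ratio choice between nested fits.

    Keeps the full model iff the LR test of the extra terms has p < alpha.
    Returns (chosen fit, p-value); the chosen fit records the decision in
    ``notes``.
    """
    extra = [t for t in fit_full.terms if t not in fit_reduced.terms]
    if not extra or any(t not in fit_full.terms for t in fit_reduced.terms):
        raise ValueError("models are not strictly nested")
    lr = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, len(extra)))
    chosen = fit_full if p < alpha else fit_reduced
    chosen.notes["interaction_terms"] = extra
    chosen.notes["interaction_p"] = p
    chosen.notes["interaction_kept"] = p < alpha
    return chosen, p


@dataclass
class RepeatabilityResult:
    r: float
    ci95: tuple[float, float]
    sigma2_point: float
    sigma2_resid: float
    n_points: int
    n_obs: int


def repeatability(
    values: Sequence[float],
    point_id: Sequence,
    measurement_kind: Optional[Sequence] = None,
    *,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> RepeatabilityResult:
    """Intraclass correlation of repeated measurements of marked points.

    Fits a Gaussian random-intercept model (point random effect, optional
    measurement-kind fixed effect) and reports
    R = sigma2_point / (sigma2_point + sigma2_resid) with a parametric
    bootstrap percentile CI.
    """
    y = np.asarray(values, dtype=float)
    pts = list(point_id)
    if len(y) != len(pts):
        raise ValueError("values and point_id lengths differ")
    upoints = list(dict.fromkeys(pts))
    if len(upoints) < 2:
        raise ValueError("need at least 2 points")
    counts: dict = {}
    for p_ in pts:
        counts[p_] = counts.get(p_, 0) + 1
    if min(counts.values()) < 2:
        raise ValueError("every point needs at least 2 repeats")
    pidx = np.array([upoints.index(p_) for p_ in pts], dtype=int)
    if measurement_kind is not None:
        kinds = list(measurement_kind)
        ukinds = list(dict.fromkeys(kinds))
        X = np.ones((len(y), len(ukinds)))
        for j, k in enumerate(ukinds[1:], start=1):
            X[:, j] = [1.0 if kk == k else 0.0 for kk in kinds]
        names = ["intercept"] + [f"kind[{k}]" for k in ukinds[1:]]
    else:
        X = np.ones((len(y), 1))
        names = ["intercept"]

    def _fit(yy: np.ndarray) -> tuple[float, float, float, np.ndarray]:
        # exact-zero within-point variance -> R = 1 by definition
        wss = 0.0
        for g in range(len(upoints)):
            sel = yy[pidx == g]
            wss += float(np.sum((sel - sel.mean()) ** 2))
        if wss <= 1e-24 * max(1.0, float(np.var(yy))):
            return 1.0, float(np.var(yy)), 0.0, np.linalg.lstsq(X, yy, rcond=None)[0]
        fit = _fit_mixed(
            X, yy, pidx, np.eye(len(upoints)), names,
            reml=True, compute_p=False,
        )
        s_a = fit.variance_components["phylogenetic"]
        s_e = fit.variance_components["residual"]
        r = s_a / (s_a + s_e) if (s_a + s_e) > 0 else 0.0
        beta = np.array([fit.coefficients[nm] for nm in names])
        return float(r), float(s_a), float(s_e), beta

    r_hat, s2a, s2e, beta = _fit(y)
    if s2e == 0.0:
        return RepeatabilityResult(1.0, (1.0, 1.0), s2a, 0.0, len(upoints), len(y))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    mu = X @ beta
    for b in range(n_boot):
        a = rng.normal(0.0, math.sqrt(s2a), size=len(upoints))
        yy = mu + a[pidx] + rng.normal(0.0, math.sqrt(s2e), size=len(y))
        boots[b] = _fit(yy)[0]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RepeatabilityResult(
        r=float(r_hat),
        ci95=(float(lo), float(hi)),
        sigma2_point=s2a,
        sigma2_resid=s2e,
        n_points=len(upoints),
        n_obs=len(y),
    )
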