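"""Phylogenetic generalized least squares with ML estimation of Pagel's lambda.

The residual covariance is sigma^2 * V(lambda), where V(1) is the
Brownian-motion matrix of shared root-to-MRCA path lengths and lambda in
[0, 1] multiplies the off-diagonal entries only (lambda = 0 collapses to
ordinary least squares on independent species).  lambda is profiled by
maximum likelihood on a 0.01 grid refined by bounded scalar optimisation;
at the optimum the GLS estimator beta = (X' V^-1 X)^-1 X' V^-1 y is
reported with a t-test on the slope (n - 2 df) and

    R^2 = 1 - RSS_V / TSS_V

where TSS_V is taken about the GLS-weighted mean — the convention of the
comparative-methods packages this mirrors, so an intercept-only null at the
same lambda-hat scores zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from .trees import ArrayTree

LAMBDA_GRID_STEP = 0.01


class PGLSError(ValueError):
    pass


def phylo_covariance(tree: ArrayTree, lam: float, species=None) -> tuple[np.ndarray, list[str]]:
    """V(lambda) over the given species (default: all tips, tree order)."""
    if not 0.0 <= lam <= 1.0:
        raise PGLSError(f"lambda must lie in [0, 1], got {lam}")
    V, labels = tree.mrca_depth_matrix()
    if species is not None:
        idx = []
        for s in species:
            if s not in labels:
                raise PGLSError(f"species {s!r} not a tree tip")
            idx.append(labels.index(s))
        V = V[np.ix_(idx, idx)]
        labels = list(species)
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out, labels


def _gls_solve(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    cf = None
    for ridge in (0.0, 1e-8, 1e-6):
        try:
            cf = cho_factor(V + ridge * float(np.mean(np.diag(V))) * np.eye(len(V)))
            if ridge:
                logging.getLogger(__name__).warning(
                    "near-singular phylogenetic covariance (duplicate "
                    "zero-length tips?): jittered diagonal by %g", ridge)
            break
        except np.linalg.LinAlgError:
            continue
    if cf is None:
        raise PGLSError("singular phylogenetic covariance even after jitter; "
                        "check for duplicated tips")
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    rss = float(resid @ cho_solve(cf, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return beta, rss, logdet, np.linalg.inv(XtViX), cf


def _profile_loglik(lam, y, X, V_full):
    n = len(y)
    V = lam * V_full
    np.fill_diagonal(V, np.diag(V_full))
    _, rss, logdet, _, _ = _gls_solve(y, X, V)
    sigma2 = rss / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


@dataclass
class PGLSFit:
    gene_id: str
    trait: str
    n: int
    lam: float
    intercept: float
    slope: float
    r2: float
    p: float
    loglik: float
    r2_clipped: bool = False


def fit_pgls(
    y, x, tree: ArrayTree, species=None, gene_id: str = "", trait: str = ""
) -> PGLSFit:
    """Regress y on x under V(lambda) with lambda profiled by ML.

    ``y`` and ``x`` are mappings species -> value or arrays aligned with
    ``species``; species with a missing value in either variable are
    dropped pairwise.  Requires at least 4 complete species.
    """
    if isinstance(y, dict) or isinstance(x, dict):
        keys = [s for s in (species or tree.tip_labels)
                if s in y and s in x
                and np.isfinite(y[s]) and np.isfinite(x[s])]
        yv = np.array([y[s] for s in keys], dtype=float)
        xv = np.array([x[s] for s in keys], dtype=float)
        species = keys
    else:
        yv = np.asarray(y, dtype=float)
        xv = np.asarray(x, dtype=float)
        if species is None:
            species = tree.tip_labels
        ok = np.isfinite(yv) & np.isfinite(xv)
        yv, xv = yv[ok], xv[ok]
        species = [s for s, k in zip(species, ok) if k]
    n = len(yv)
    if n < 4:
        raise PGLSError(f"insufficient data: {n} complete species, need >= 4")

    V_full, _ = phylo_covariance(tree, 1.0, species)
    X = np.column_stack([np.ones(n), xv])

    grid = np.arange(0.0, 1.0 + 1e-9, LAMBDA_GRID_STEP)
    lls = np.array([_profile_loglik(l, yv, X, V_full) for l in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda l: -_profile_loglik(l, yv, X, V_full),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        lam = float(res.x) if -res.fun >= lls[best] else float(grid[best])
    else:  # pragma: no cover
        lam = float(grid[best])

    V = lam * V_full
    np.fill_diagonal(V, np.diag(V_full))
    beta, rss, _, XtViX_inv, cf = _gls_solve(yv, X, V)

    ones = np.ones(n)
    Vi_1 = cho_solve(cf, ones)
    mu = float((Vi_1 @ yv) / (Vi_1 @ ones))
    dev = yv - mu
    tss = float(dev @ cho_solve(cf, dev))
    r2_clipped = False
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if r2 < 0:
        r2, r2_clipped = 0.0, True
    r2 = min(r2, 1.0)

    sigma2 = rss / (n - 2)
    scale = max(float(np.abs(yv).max()), 1.0)
    if sigma2 <= 1e-20 * scale**2:  # degenerate: (near-)perfect or constant fit
        p = 1.0 if abs(beta[1]) < 1e-8 * scale else 0.0
    else:
        se_slope = float(np.sqrt(sigma2 * XtViX_inv[1, 1]))
        tval = beta[1] / se_slope
        p = float(2.0 * t_dist.sf(abs(tval), n - 2))
    return PGLSFit(
        gene_id=gene_id, trait=trait, n=n, lam=lam,
        intercept=float(beta[0]), slope=float(beta[1]),
        r2=float(r2), p=p, loglik=_profile_loglik(lam, yv, X, V_full),
        r2_clipped=r2_clipped,
    )


def regress_all(
    omega_table: pd.DataFrame,
    traits: pd.DataFrame,
    tree: ArrayTree,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One log10-log10 PGLS per gene x trait.

    ``omega_table``: rows = species (index), columns = genes, values =
    root-to-tip omega.  ``traits``: columns species, mls_years, bm_g.
    Traits and omegas are log10-transformed; omega <= 0 or missing drops
    the species for that gene.  Significance column uses raw p < alpha (a
    BH-adjusted column is emitted alongside).
    """
    from .selection import bh_fdr
    from .traits import compute_lq

    tr = traits.set_index("species")
    trait_values = {
        "MLS": tr["mls_years"].to_dict(),
        "BM": tr["bm_g"].to_dict(),
        "LQ": {s: compute_lq(r["mls_years"], r["bm_g"]) for s, r in tr.iterrows()},
    }
    rows = []
    for gene in omega_table.columns:
        omega = omega_table[gene].to_dict()
        y = {s: np.log10(v) for s, v in omega.items()
             if np.isfinite(v) and v > 0}
        if not y:
            continue
        for trait, values in trait_values.items():
            x = {s: np.log10(v) for s, v in values.items() if v > 0}
            try:
                fit = fit_pgls(y, x, tree, gene_id=gene, trait=trait)
            except PGLSError:
                continue
            rows.append({"gene": gene, "trait": trait, "n": fit.n,
                         "lambda": fit.lam, "slope": fit.slope,
                         "intercept": fit.intercept, "R2": fit.r2, "p": fit.p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_bh"] = bh_fdr(df["p"])
        df["significant"] = df["p"] < alpha
    return df
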