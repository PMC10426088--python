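"""Codon substitution models and maximum-likelihood fitting.

Models
------
M0            one dN/dS ratio (omega) for all sites and branches
M8 / M8a      ten equal-probability beta(p,q) categories of omega in (0,1)
              plus one extra class with omega > 1 (M8) or fixed at 1 (M8a)
BS_A / BS_A_NULL
              branch-site model A: classes 0 (omega0 < 1 everywhere),
              1 (neutral), 2a/2b (omega2 on the foreground branches only);
              the null pins omega2 at 1
BUSTED_ALT / BUSTED_NULL
              episodic three-class mixture: omega1 <= omega2 <= 1 shared by
              all branches, a third class neutral on the background and
              omega3 >= 1 on the foreground; the null pins omega3 at 1 (no
              synonymous rate variation — a deliberate simplification)
FREE_RATIO    an independent omega per branch, shared kappa

Free parameters are optimised with bounded L-BFGS-B in transformed space
(log for rates, softmax logits for class proportions) with a fixed set of
restart seeds; branch lengths are estimated once under M0 by coordinate
ascent and held fixed for every other model of the same gene, which keeps
the likelihood surface low-dimensional without altering model nesting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import beta as beta_dist

from .alignments import CodonAlignment
from .likelihood import (
    PatternData,
    branch_transition_tensor,
    class_transition_tensor,
    mixture_loglik,
    prune_class_loglik,
)
from .ratematrix import f3x4_frequencies, floor_pi, nonsyn_rate_fraction
from .trees import ArrayTree

logger = logging.getLogger(__name__)

KAPPA_BOUNDS = (0.1, 20.0)
OMEGA_BOUNDS = (1e-4, 50.0)
BETA_BOUNDS = (0.005, 100.0)
N_BETA_CATEGORIES = 10
LOGIT_BOUND = 12.0
RESTART_SEEDS = (0, 1, 2)

MODEL_NAMES = (
    "M0", "M8", "M8A", "BS_A", "BS_A_NULL",
    "BUSTED_ALT", "BUSTED_NULL", "FREE_RATIO",
)


class FitError(RuntimeError):
    pass


def _softmax(z: np.ndarray) -> np.ndarray:
    full = np.concatenate([z, [0.0]])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def beta_category_omegas(p: float, q: float, k: int = N_BETA_CATEGORIES) -> np.ndarray:
    """Medians of k equal-probability categories of a beta(p, q) on (0, 1)."""
    quantiles = (np.arange(k) + 0.5) / k
    return np.clip(beta_dist.ppf(quantiles, p, q), 1e-6, 1.0 - 1e-6)


@dataclass
class ModelDef:
    """A model's free-parameter space and its mapping to site classes."""

    name: str
    x0: np.ndarray
    bounds: list[tuple[float, float]]
    unpack: Callable[[np.ndarray], tuple[float, list[tuple[float, float, float]], dict]]
    positive_classes: tuple[int, ...] = ()
    uses_foreground: bool = False

    @property
    def n_params(self) -> int:
        return len(self.x0)


def _log_bounds(lo: float, hi: float) -> tuple[float, float]:
    return (np.log(lo), np.log(hi))


def model_def(name: str) -> ModelDef:
    name = name.upper()
    kx = np.log(2.0)
    kb = _log_bounds(*KAPPA_BOUNDS)
    if name == "M0":
        def unpack(x):
            kappa, omega = np.exp(x)
            return kappa, [(1.0, omega, omega)], {"omega": omega}
        return ModelDef("M0", np.array([kx, np.log(0.4)]),
                        [kb, _log_bounds(*OMEGA_BOUNDS)], unpack)
    if name in ("M8", "M8A"):
        is_m8 = name == "M8"
        def unpack(x):
            kappa = np.exp(x[0])
            p, q = np.exp(x[1]), np.exp(x[2])
            w = _softmax(x[3:4])           # (p0, p1)
            omega_s = 1.0 + np.exp(x[4]) if is_m8 else 1.0
            cats = beta_category_omegas(p, q)
            classes = [(w[0] / len(cats), om, om) for om in cats]
            classes.append((w[1], omega_s, omega_s))
            return kappa, classes, {"p": p, "q": q, "p0": w[0], "p1": w[1],
                                    "omega_s": omega_s}
        x0 = [kx, np.log(1.0), np.log(2.0), 2.0]
        bounds = [kb, _log_bounds(*BETA_BOUNDS), _log_bounds(*BETA_BOUNDS),
                  (-LOGIT_BOUND, LOGIT_BOUND)]
        if is_m8:
            x0.append(np.log(1.0))         # omega_s = 2
            bounds.append(_log_bounds(1e-6, OMEGA_BOUNDS[1] - 1.0))
        return ModelDef(name, np.array(x0), bounds, unpack,
                        positive_classes=(N_BETA_CATEGORIES,) if is_m8 else ())
    if name in ("BS_A", "BS_A_NULL"):
        is_alt = name == "BS_A"
        def unpack(x):
            kappa = np.exp(x[0])
            omega0 = np.exp(x[1])
            w = _softmax(x[2:4])           # (p0, p1, p2_total)
            omega2 = 1.0 + np.exp(x[4]) if is_alt else 1.0
            p0, p1, p2 = w
            denom = max(p0 + p1, 1e-12)
            p2a, p2b = p2 * p0 / denom, p2 * p1 / denom
            classes = [(p0, omega0, omega0), (p1, 1.0, 1.0),
                       (p2a, omega0, omega2), (p2b, 1.0, omega2)]
            return kappa, classes, {"omega0": omega0, "omega2": omega2,
                                    "p0": p0, "p1": p1, "p2a": p2a, "p2b": p2b}
        x0 = [kx, np.log(0.2), 1.2, 0.1]
        bounds = [kb, _log_bounds(1e-4, 0.999),
                  (-LOGIT_BOUND, LOGIT_BOUND), (-LOGIT_BOUND, LOGIT_BOUND)]
        if is_alt:
            x0.append(np.log(1.0))
            bounds.append(_log_bounds(1e-6, OMEGA_BOUNDS[1] - 1.0))
        return ModelDef(name, np.array(x0), bounds, unpack,
                        positive_classes=(2, 3) if is_alt else (),
                        uses_foreground=True)
    if name in ("BUSTED_ALT", "BUSTED_NULL"):
        is_alt = name == "BUSTED_ALT"
        def unpack(x):
            kappa = np.exp(x[0])
            omega2 = np.exp(x[1])          # in (0, 1)
            omega1 = omega2 * _sigmoid(x[2])
            w = _softmax(x[3:5])           # (w1, w2, w3)
            omega3 = 1.0 + np.exp(x[5]) if is_alt else 1.0
            classes = [(w[0], omega1, omega1), (w[1], omega2, omega2),
                       (w[2], 1.0, omega3)]
            return kappa, classes, {"omega1": omega1, "omega2": omega2,
                                    "omega3": omega3, "w1": w[0], "w2": w[1],
                                    "w3": w[2]}
        x0 = [kx, np.log(0.5), -2.0, 2.0, 1.0]
        bounds = [kb, _log_bounds(1e-4, 0.999), (-LOGIT_BOUND, LOGIT_BOUND),
                  (-LOGIT_BOUND, LOGIT_BOUND), (-LOGIT_BOUND, LOGIT_BOUND)]
        if is_alt:
            x0.append(np.log(1.0))
            bounds.append(_log_bounds(1e-6, OMEGA_BOUNDS[1] - 1.0))
        return ModelDef(name, np.array(x0), bounds, unpack,
                        positive_classes=(2,) if is_alt else (),
                        uses_foreground=True)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


@dataclass
class ModelFit:
    """A fitted codon model: parameters, likelihood and site posteriors."""

    model: str
    lnl: float
    kappa: float
    params: dict
    classes: list[tuple[float, float, float]]  # (weight, omega_bg, omega_fg)
    tree: ArrayTree
    pi: np.ndarray
    x: np.ndarray
    converged: bool
    n_iter: int
    site_posteriors: np.ndarray | None = None  # (n_classes, n_sites)
    positive_classes: tuple[int, ...] = ()
    branch_table: pd.DataFrame | None = None   # FREE_RATIO only

    def to_dict(self) -> dict:
        out = {
            "schema_version": 1,
            "model": self.model,
            "lnl": self.lnl,
            "kappa": self.kappa,
            "params": {k: float(v) for k, v in self.params.items()},
            "classes": [[float(v) for v in c] for c in self.classes],
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }
        if self.branch_table is not None:
            out["branches"] = self.branch_table.to_dict(orient="records")
        return out


def make_objective(data: PatternData, mdef: ModelDef, pi: np.ndarray):
    """Return ``neg_loglik(x)`` and ``posteriors(x)`` for a model/dataset."""
    pi = floor_pi(pi)

    def evaluate(x):
        kappa, classes, _ = mdef.unpack(np.asarray(x, dtype=float))
        weights = [c[0] for c in classes]
        P = class_transition_tensor(
            data.tree, kappa, pi, [(w, ob, of) for (w, ob, of) in classes]
        )
        cl = prune_class_loglik(data, P, pi)
        return mixture_loglik(cl, weights, data.counts)

    def neg_loglik(x) -> float:
        total, _, _ = evaluate(x)
        if not np.isfinite(total):
            return 1e12
        return -total

    def posteriors(x) -> np.ndarray:
        _, _, post = evaluate(x)
        return data.expand(post)

    return neg_loglik, posteriors


def fit_model(
    aln: CodonAlignment,
    tree: ArrayTree,
    model: str,
    foreground=(),
    pi: np.ndarray | None = None,
    n_restarts: int = 3,
    warm_starts=(),
    compute_posteriors: bool = True,
) -> ModelFit:
    """Maximise the likelihood of one codon model with fixed branch lengths.

    ``foreground`` is a set of tip labels whose terminal branches form the
    foreground of branch-site-style models (ignored by site models).
    Restarts use the fixed seeds 0, 1, 2 …; ``warm_starts`` adds extra
    starting vectors (e.g. a nested null's solution embedded in the
    alternative's space).  A fit that never converges is returned flagged,
    never silently.
    """
    mdef = model_def(model)
    if mdef.uses_foreground:
        if not foreground:
            raise FitError(f"{mdef.name} requires a non-empty foreground")
        tree = tree.with_foreground(foreground)
    pi = f3x4_frequencies(aln.codons) if pi is None else floor_pi(pi)
    data = PatternData.from_alignment(aln, tree)
    neg_loglik, posteriors = make_objective(data, mdef, pi)

    starts = [mdef.x0]
    for seed in RESTART_SEEDS[: max(n_restarts - 1, 0)]:
        rng = np.random.default_rng(seed)
        starts.append(mdef.x0 + rng.normal(0.0, 0.4, size=mdef.n_params))
    starts.extend(np.asarray(w, dtype=float) for w in warm_starts)
    lo = np.array([b[0] for b in mdef.bounds])
    hi = np.array([b[1] for b in mdef.bounds])

    best = None
    any_converged = False
    total_iter = 0
    for x0 in starts:
        res = minimize(
            neg_loglik, np.clip(x0, lo, hi), method="L-BFGS-B",
            bounds=mdef.bounds,
            options={"maxiter": 150, "ftol": 1e-8},
        )
        total_iter += res.nit
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:  # pragma: no cover
        raise FitError(f"{mdef.name}: no optimisation attempt completed")
    if not any_converged:
        logger.warning("%s on %s: optimiser did not report convergence",
                       mdef.name, aln.gene_id)

    kappa, classes, params = mdef.unpack(best.x)
    fit = ModelFit(
        model=mdef.name, lnl=-float(best.fun), kappa=float(kappa),
        params=params, classes=classes, tree=tree, pi=pi, x=best.x.copy(),
        converged=any_converged, n_iter=total_iter,
        positive_classes=mdef.positive_classes,
    )
    if compute_posteriors:
        fit.site_posteriors = posteriors(best.x)
    return fit


# -- branch lengths under M0 --------------------------------------------------

def estimate_branch_lengths(
    aln: CodonAlignment,
    tree: ArrayTree,
    pi: np.ndarray | None = None,
    max_sweeps: int = 6,
    tol: float = 1e-3,
    max_branch_length: float = 10.0,
) -> tuple[ArrayTree, ModelFit]:
    """One M0 pass: jointly estimate kappa, omega and all branch lengths.

    Alternates a 2-parameter quasi-Newton step for (kappa, omega) with a
    Brent line search per branch until the log-likelihood gain per sweep
    drops below ``tol``.  Returns the tree with fitted lengths plus the M0
    fit; every subsequent model of the same gene holds these lengths fixed.
    """
    pi = f3x4_frequencies(aln.codons) if pi is None else floor_pi(pi)
    work = tree.with_branch_lengths(tree.branch_lengths.copy())
    data = PatternData.from_alignment(aln, work)  # patterns ignore lengths
    mdef = model_def("M0")
    x = mdef.x0.copy()

    def lnl_for(x_params, lengths):
        t = work.with_branch_lengths(lengths)
        kappa, classes, _ = mdef.unpack(x_params)
        P = class_transition_tensor(t, kappa, pi, classes)
        cl = prune_class_loglik(data, P, pi)
        total, _, _ = mixture_loglik(cl, [c[0] for c in classes], data.counts)
        return total

    lengths = work.branch_lengths.copy()
    lengths[lengths <= 0] = 1e-4
    lengths[work.root] = 0.0
    current = lnl_for(x, lengths)
    from .ratematrix import cached_spectral, expected_rate, rate_matrix_unscaled

    for sweep in range(max_sweeps):
        res = minimize(lambda xv: -lnl_for(xv, lengths), x, method="L-BFGS-B",
                       bounds=mdef.bounds, options={"maxiter": 60, "ftol": 1e-9})
        x = res.x
        # per-branch line search; only that branch's transition slab changes
        kappa, classes, _ = mdef.unpack(x)
        t = work.with_branch_lengths(lengths)
        P = class_transition_tensor(t, kappa, pi, classes)
        r = expected_rate(rate_matrix_unscaled(kappa, classes[0][1], pi), pi)
        spectral = cached_spectral(kappa, classes[0][1], r, pi)

        def branch_nll(tb, b):
            P[0, b] = spectral.probs(tb)
            cl = prune_class_loglik(data, P, pi)
            total, _, _ = mixture_loglik(cl, [1.0], data.counts)
            return -total

        for b in range(work.n_nodes - 1):
            res_b = minimize_scalar(
                branch_nll, args=(b,), bounds=(1e-8, max_branch_length),
                method="bounded", options={"xatol": 1e-5, "maxiter": 40},
            )
            lengths[b] = float(res_b.x)
            P[0, b] = spectral.probs(lengths[b])
        new = lnl_for(x, lengths)
        if new - current < tol:
            current = new
            break
        current = new

    fitted_tree = work.with_branch_lengths(lengths)
    kappa, classes, params = mdef.unpack(x)
    fit = ModelFit(
        model="M0", lnl=float(current), kappa=float(kappa), params=params,
        classes=classes, tree=fitted_tree, pi=pi, x=np.asarray(x),
        converged=True, n_iter=max_sweeps,
    )
    return fitted_tree, fit


# -- free-ratio ---------------------------------------------------------------

def fit_free_ratio(
    aln: CodonAlignment,
    tree: ArrayTree,
    pi: np.ndarray | None = None,
    max_sweeps: int = 4,
    tol: float = 1e-3,
) -> ModelFit:
    """One omega per branch (shared kappa), branch lengths held fixed.

    Per-branch dN and dS apportion each branch length by the fitted
    generator's nonsynonymous flux fraction, so dN + dS equals the branch
    length and path sums are directly comparable across branches.
    """
    pi = f3x4_frequencies(aln.codons) if pi is None else floor_pi(pi)
    data = PatternData.from_alignment(aln, tree)
    n = tree.n_nodes
    omegas = np.full(n, 0.3)
    kappa = 2.0
    P = branch_transition_tensor(tree, kappa, pi, omegas)

    def total_lnl():
        cl = prune_class_loglik(data, P, pi)
        total, _, _ = mixture_loglik(cl, [1.0], data.counts)
        return total

    def rebuild(k):
        nonlocal P
        P = branch_transition_tensor(tree, k, pi, omegas)

    current = total_lnl()
    from .ratematrix import SpectralQ, rate_matrix_unscaled, expected_rate

    for sweep in range(max_sweeps):
        # shared kappa
        def kappa_nll(logk):
            rebuild(float(np.exp(logk)))
            return -total_lnl()

        res_k = minimize_scalar(kappa_nll,
                                bounds=(np.log(KAPPA_BOUNDS[0]), np.log(KAPPA_BOUNDS[1])),
                                method="bounded", options={"xatol": 1e-4})
        kappa = float(np.exp(res_k.x))
        rebuild(kappa)

        for b in range(n - 1):
            tb = tree.branch_lengths[b]
            if tb <= 1e-9:
                omegas[b] = 1.0  # inert branch, omega unidentifiable
                continue

            def omega_nll(logw, b=b, tb=tb):
                om = float(np.exp(logw))
                Q = rate_matrix_unscaled(kappa, om, pi)
                Q /= expected_rate(Q, pi)
                P[0, b] = SpectralQ(Q, pi).probs(tb)
                return -total_lnl()

            res_b = minimize_scalar(
                omega_nll,
                bounds=(np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1])),
                method="bounded", options={"xatol": 1e-3, "maxiter": 30},
            )
            omegas[b] = float(np.exp(res_b.x))
            omega_nll(res_b.x, b, tb)  # leave P consistent with the optimum
        new = total_lnl()
        if new - current < tol:
            current = new
            break
        current = new

    rows = []
    for b in range(n - 1):
        tb = float(tree.branch_lengths[b])
        om = float(omegas[b])
        if tb <= 1e-9:
            dn = ds = 0.0
        else:
            rho_n = nonsyn_rate_fraction(kappa, om, pi)
            dn, ds = tb * rho_n, tb * (1.0 - rho_n)
        rows.append({"node": b, "label": tree.labels[b] or "",
                     "t": tb, "omega": om, "dn": dn, "ds": ds})
    table = pd.DataFrame(rows)
    return ModelFit(
        model="FREE_RATIO", lnl=float(current), kappa=kappa,
        params={"n_branches": n - 1}, classes=[(1.0, float("nan"), float("nan"))],
        tree=tree, pi=pi, x=np.log(np.maximum(omegas, 1e-8)), converged=True,
        n_iter=max_sweeps, branch_table=table,
    )


# -- nested pairs -------------------------------------------------------------

_NULL_OF = {"M8": "M8A", "BS_A": "BS_A_NULL", "BUSTED_ALT": "BUSTED_NULL"}


def _embed_null(alt_name: str, null_fit: ModelFit) -> np.ndarray:
    """Lift a null solution into the alternative's parameter space with the
    extra positive-selection omega started at its lower bound (1 + 1e-6), so
    the alternative's starting log-likelihood matches the null's."""
    eps = np.log(1e-6)
    return np.concatenate([null_fit.x, [eps]])


def fit_nested_pair(
    aln: CodonAlignment,
    tree: ArrayTree,
    alt: str,
    foreground=(),
    pi: np.ndarray | None = None,
    n_restarts: int = 2,
) -> tuple[ModelFit, ModelFit]:
    """Fit a null model and its alternative, warm-starting the alternative
    at the null optimum so the nesting inequality holds numerically."""
    alt = alt.upper()
    null_name = _NULL_OF[alt]
    null_fit = fit_model(aln, tree, null_name, foreground=foreground, pi=pi,
                         n_restarts=n_restarts, compute_posteriors=False)
    alt_fit = fit_model(
        aln, tree, alt, foreground=foreground, pi=pi, n_restarts=n_restarts,
        warm_starts=[_embed_null(alt, null_fit)],
    )
    return alt_fit, null_fit
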