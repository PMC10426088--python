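"""Likelihood-ratio testing, FDR control, selected-site identification,
the candidate-gene decision rule and root-to-tip omega extraction.

A gene is a candidate for positive selection unique to the long-lived
species when (i) the branch-site test is significant for at least one
long-lived lineage, (ii) the episodic (BUSTED-style) test agrees for at
least one long-lived lineage, and (iii) the M8-vs-M8a site-model contrast
restricted to the control species shows nothing — evidence in the control
group disqualifies the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .alignments import CodonAlignment
from .likelihood import PatternData
from .models import LOGIT_BOUND, FitError, ModelFit, make_objective, model_def
from .ratematrix import floor_pi
from .trees import ArrayTree

CONTROL_SITE_MODEL = "control-site-model"
DEFAULT_ALPHA = 0.05
DEFAULT_PP_CUTOFF = 0.80

#: degrees of freedom per test (chi2 null; conservative conventions)
TEST_DF = {"PAML_BS": 1, "M8_VS_M8A": 1, "BUSTED_LIKE": 2}

LNL_TOLERANCE = 1e-4


class SelectionInputError(ValueError):
    pass


@dataclass
class SiteHit:
    column: int                 # 1-based alignment codon column
    reference_position: int | None
    posterior: float


@dataclass
class SelectionTestResult:
    gene_id: str
    lineage: str                # foreground species or "control-site-model"
    method: str                 # PAML_BS | BUSTED_LIKE | M8_VS_M8A
    stat: float
    df: int
    p: float
    q: float | None = None
    significant: bool | None = None
    sites: list[SiteHit] = field(default_factory=list)


def lrt(lnl_alt: float, lnl_null: float, df: int,
        boundary_mixture: bool = False,
        tol: float = LNL_TOLERANCE) -> tuple[float, float]:
    """2*(lnL_alt - lnL_null) against a chi-square with ``df`` degrees.

    ``boundary_mixture`` uses the 50:50 mixture of chi2(df-1) and chi2(df)
    appropriate when the constrained parameter sits on the boundary of the
    alternative's space (the asymptotic null of the branch-site test);
    plain chi2(df) is the conservative convention.

    Tiny negative statistics (within ``tol``) are numerical noise and clip
    to zero; anything worse means the alternative's optimiser failed and a
    refit is demanded rather than reporting a bogus p-value.
    """
    delta = lnl_alt - lnl_null
    if delta < -tol:
        raise FitError(
            f"alternative lnL {lnl_alt:.6f} below null {lnl_null:.6f}: "
            "optimiser failure, refit required"
        )
    stat = max(2.0 * delta, 0.0)
    if boundary_mixture:
        lower = float(chi2.sf(stat, df - 1)) if df > 1 else (1.0 if stat <= 0 else 0.0)
        p = 0.5 * lower + 0.5 * float(chi2.sf(stat, df))
    else:
        p = float(chi2.sf(stat, df))
    return stat, min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (empty in, empty out)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise SelectionInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: list[SelectionTestResult], alpha: float = DEFAULT_ALPHA,
              scope: str = "method") -> None:
    """Attach q-values and significance flags in place.

    ``scope='method'`` corrects across all gene-by-lineage tests within each
    method (the default); ``'global'`` pools every test.
    """
    if scope not in ("method", "global"):
        raise SelectionInputError(f"unknown FDR scope {scope!r}")
    groups: dict[str, list[SelectionTestResult]] = {}
    for r in results:
        key = r.method if scope == "method" else "all"
        groups.setdefault(key, []).append(r)
    for rs in groups.values():
        qs = bh_fdr([r.p for r in rs])
        for r, q in zip(rs, qs):
            r.q = float(q)
            r.significant = bool(q < alpha)


# -- empirical-Bayes site identification --------------------------------------

def _hessian_diag(fun, x: np.ndarray, indices, h: float = 5e-3) -> np.ndarray:
    f0 = fun(x)
    out = np.empty(len(indices))
    for k, i in enumerate(indices):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        out[k] = (fun(xp) + fun(xm) - 2.0 * f0) / h**2
    return out


def site_posteriors(
    fit: ModelFit,
    aln: CodonAlignment,
    cutoff: float = DEFAULT_PP_CUTOFF,
    strict: bool = True,
    grid_points: int = 5,
    max_step: float = 1.5,
) -> list[SiteHit]:
    """Sites assigned to the positive-selection class with high posterior.

    The posterior that a column belongs to an omega > 1 class is averaged
    over a uniform grid of ``grid_points`` values per parameter spanning
    +/- 2 SE (capped) around the MLE of the class-proportion logits and the
    positive omega, in transformed space — a coarse empirical-Bayes
    integration of parameter uncertainty.  ``strict`` keeps PP > cutoff;
    PP >= cutoff otherwise.
    """
    if not fit.positive_classes:
        raise SelectionInputError(
            f"model {fit.model} has no omega > 1 class; site test not applicable"
        )
    mdef = model_def(fit.model)
    data = PatternData.from_alignment(aln, fit.tree)
    neg_loglik, posteriors = make_objective(data, mdef, floor_pi(fit.pi))

    # parameters integrated over: proportion logits + the trailing omega
    logit_idx = [i for i, b in enumerate(mdef.bounds)
                 if b == (-LOGIT_BOUND, LOGIT_BOUND)]
    idx = sorted(set(logit_idx + [mdef.n_params - 1]))
    hess = _hessian_diag(neg_loglik, fit.x, idx)
    se = 1.0 / np.sqrt(np.maximum(hess, 1e-6))
    steps = np.minimum(2.0 * se, max_step)

    lo = np.array([mdef.bounds[i][0] for i in idx])
    hi = np.array([mdef.bounds[i][1] for i in idx])
    offsets = np.linspace(-1.0, 1.0, grid_points)
    grids = [np.clip(fit.x[i] + offsets * s, l, h)
             for i, s, l, h in zip(idx, steps, lo, hi)]

    acc = np.zeros(aln.n_columns)
    count = 0
    mesh = np.meshgrid(*grids, indexing="ij")
    for point in zip(*(m.ravel() for m in mesh)):
        x = fit.x.copy()
        for i, v in zip(idx, point):
            x[i] = v
        post = posteriors(x)  # (C, n_sites)
        acc += post[list(fit.positive_classes)].sum(axis=0)
        count += 1
    pp = acc / count

    hits = []
    for col in range(aln.n_columns):
        keep = pp[col] > cutoff if strict else pp[col] >= cutoff
        if keep:
            hits.append(SiteHit(column=col + 1, reference_position=None,
                                posterior=float(pp[col])))
    return hits


# -- candidate rule -----------------------------------------------------------

@dataclass
class CandidateGeneReport:
    gene_id: str
    branch_site_lineages: list[str]     # lineages significant under PAML_BS
    busted_lineages: list[str]          # lineages significant under BUSTED_LIKE
    control_m8_significant: bool
    candidate: bool


def candidate_genes(
    results: list[SelectionTestResult], alpha: float = DEFAULT_ALPHA
) -> list[CandidateGeneReport]:
    """Apply the consensus-minus-control rule per gene.

    Requires every result to already carry a significance flag (run
    :func:`apply_fdr` first; the control M8 contrast keeps its own flag) and
    exactly one control-group site-model result per gene — a missing control
    result is an error, never assumed non-significant.
    """
    genes = sorted({r.gene_id for r in results})
    reports = []
    for gene in genes:
        rs = [r for r in results if r.gene_id == gene]
        control = [r for r in rs if r.lineage == CONTROL_SITE_MODEL]
        if len(control) != 1:
            raise SelectionInputError(
                f"{gene}: need exactly one control-group M8 result, got {len(control)}"
            )
        for r in rs:
            if r.significant is None:
                raise SelectionInputError(f"{gene}: result lacks significance flag")
        bs = sorted(r.lineage for r in rs
                    if r.method == "PAML_BS" and r.significant)
        bu = sorted(r.lineage for r in rs
                    if r.method == "BUSTED_LIKE" and r.significant)
        ctrl_sig = bool(control[0].significant)
        reports.append(CandidateGeneReport(
            gene_id=gene, branch_site_lineages=bs, busted_lineages=bu,
            control_m8_significant=ctrl_sig,
            candidate=bool(bs) and bool(bu) and not ctrl_sig,
        ))
    return reports


# -- root-to-tip omega --------------------------------------------------------

def root_to_tip_omega(free_fit: ModelFit, tree: ArrayTree | None = None) -> dict:
    """Per-tip omega: summed dN over the root-to-tip path divided by summed
    dS; tips whose whole path has dS = 0 come back as NaN (missing)."""
    if free_fit.branch_table is None:
        raise SelectionInputError("free-ratio fit with per-branch dN/dS required")
    tree = free_fit.tree if tree is None else tree
    table = free_fit.branch_table.set_index("node")
    out = {}
    for tip in tree.tip_indices:
        path = tree.path_to_root(tip)
        dn = float(table.loc[path, "dn"].sum())
        ds = float(table.loc[path, "ds"].sum())
        out[tree.labels[tip]] = dn / ds if ds > 0 else float("nan")
    return out


def results_table(results: list[SelectionTestResult]) -> pd.DataFrame:
    rows = [{
        "gene": r.gene_id, "lineage": r.lineage, "method": r.method,
        "stat": r.stat, "df": r.df, "p": r.p, "q": r.q,
        "significant": r.significant, "n_sites": len(r.sites),
    } for r in results]
    return pd.DataFrame(rows)
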