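"""LRT, BH-FDR, candidate rule, site posteriors, root-to-tip omega."""

import itertools

import numpy as np
import pytest

import longevol as lv
from longevol.models import FitError, estimate_branch_lengths, fit_nested_pair
from longevol.selection import (
    CONTROL_SITE_MODEL,
    SelectionTestResult,
    SelectionInputError,
    apply_fdr,
    bh_fdr,
    candidate_genes,
    lrt,
    root_to_tip_omega,
    site_posteriors,
)
from longevol.trees import ArrayTree


# -- LRT ----------------------------------------------------------------------

def test_lrt_zero_statistic():
    stat, p = lrt(-1000.0, -1000.0, 1)
    assert stat == 0.0 and p == 1.0


@pytest.mark.parametrize("stat, df, expected", [
    (3.841, 1, 0.050), (5.991, 2, 0.050),
])
def test_lrt_chi2_critical_values(stat, df, expected):
    _, p = lrt(-1000.0 + stat / 2, -1000.0, df)
    assert p == pytest.approx(expected, abs=5e-4)


def test_lrt_boundary_mixture_halves_the_tail():
    _, p_plain = lrt(-998.0, -1000.0, 1)
    _, p_mix = lrt(-998.0, -1000.0, 1, boundary_mixture=True)
    assert p_mix == pytest.approx(0.5 * p_plain)
    _, p0 = lrt(-1000.0, -1000.0, 1, boundary_mixture=True)
    assert p0 == 1.0


def test_lrt_rejects_optimizer_failure():
    with pytest.raises(FitError, match="refit"):
        lrt(-1001.0, -1000.0, 1)


# -- BH-FDR -------------------------------------------------------------------

def brute_force_bh(p):
    """Step-up definition: q_i = min_{j: p_j >= p_i} p_j * m / rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def test_bh_hand_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases():
    assert bh_fdr([]).size == 0
    assert bh_fdr([0.03])[0] == pytest.approx(0.03)
    assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)


def test_bh_equals_step_up_oracle_exhaustively():
    grid = np.round(np.arange(0.0, 1.01, 0.25), 2)
    for m in range(1, 5):
        for combo in itertools.product(grid, repeat=m):
            assert np.allclose(bh_fdr(list(combo)), brute_force_bh(combo)), combo
    rng = np.random.default_rng(0)
    for _ in range(200):
        p = np.round(rng.integers(0, 101, size=6) / 100, 2)
        assert np.allclose(bh_fdr(p), brute_force_bh(p))


def test_bh_rejects_invalid():
    with pytest.raises(SelectionInputError):
        bh_fdr([0.5, 1.5])


# -- candidate rule -----------------------------------------------------------

def make_result(gene, lineage, method, significant):
    r = SelectionTestResult(gene, lineage, method, 1.0, 1, 0.5)
    r.significant = significant
    r.q = 0.5
    return r


def oracle_candidate(bs_sig, bu_sig, ctrl_sig):
    return (any(bs_sig) and any(bu_sig)) and not ctrl_sig


def test_candidate_rule_matches_boolean_oracle_on_random_tables():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n_lin = int(rng.integers(1, 4))
        bs = rng.random(n_lin) < 0.4
        bu = rng.random(n_lin) < 0.4
        ctrl = bool(rng.random() < 0.3)
        results = [make_result("G", f"L{k}", "PAML_BS", bool(bs[k]))
                   for k in range(n_lin)]
        results += [make_result("G", f"L{k}", "BUSTED_LIKE", bool(bu[k]))
                    for k in range(n_lin)]
        results.append(make_result("G", CONTROL_SITE_MODEL, "M8_VS_M8A", ctrl))
        (report,) = candidate_genes(results)
        assert report.candidate == oracle_candidate(bs, bu, ctrl)


def test_candidate_rule_control_veto():
    results = [
        make_result("G", "L1", "PAML_BS", True),
        make_result("G", "L1", "BUSTED_LIKE", True),
        make_result("G", CONTROL_SITE_MODEL, "M8_VS_M8A", True),
    ]
    (report,) = candidate_genes(results)
    assert not report.candidate
    results[-1] = make_result("G", CONTROL_SITE_MODEL, "M8_VS_M8A", False)
    (report,) = candidate_genes(results)
    assert report.candidate


def test_candidate_rule_missing_control_is_error():
    results = [make_result("G", "L1", "PAML_BS", True),
               make_result("G", "L1", "BUSTED_LIKE", True)]
    with pytest.raises(SelectionInputError, match="control"):
        candidate_genes(results)


def test_candidacy_monotone_in_pvalues():
    """Lowering a branch-test p-value never removes candidacy."""
    base_p = [0.01, 0.2, 0.01, 0.3]
    for smaller in range(4):
        ps = list(base_p)
        results = []
        for k, method in enumerate(["PAML_BS", "PAML_BS",
                                    "BUSTED_LIKE", "BUSTED_LIKE"]):
            r = SelectionTestResult("G", f"L{k % 2}", method, 1.0, 1, ps[k])
            results.append(r)
        ctrl = make_result("G", CONTROL_SITE_MODEL, "M8_VS_M8A", False)
        apply_fdr(results, alpha=0.05)
        before = candidate_genes(results + [ctrl])[0].candidate
        results2 = [SelectionTestResult(r.gene_id, r.lineage, r.method, r.stat,
                                        r.df, r.p if k != smaller else r.p / 10)
                    for k, r in enumerate(results)]
        apply_fdr(results2, alpha=0.05)
        after = candidate_genes(results2 + [ctrl])[0].candidate
        assert after >= before


def test_apply_fdr_scopes():
    results = [SelectionTestResult("G", f"L{i}", m, 1.0, 1, p)
               for m, ps in [("PAML_BS", [0.01, 0.04]),
                             ("BUSTED_LIKE", [0.2, 0.8])]
               for i, p in enumerate(ps)]
    apply_fdr(results, alpha=0.05, scope="method")
    per_method = [r.q for r in results]
    apply_fdr(results, alpha=0.05, scope="global")
    pooled = [r.q for r in results]
    assert per_method[0] <= pooled[0]  # pooling with big p-values hurts
    for r in results:
        assert r.q >= r.p


# -- site posteriors ----------------------------------------------------------

def test_site_posteriors_recover_planted_sites():
    """Branch-site simulation with a hot foreground class: most truly
    selected sites found at PP > 0.8, few false sites."""
    tree = lv.simulate_tree(12, seed=31, mean_root_to_tip=0.5)
    fg = tree.tip_labels[:4]
    fg_tree = tree.with_foreground(fg)
    classes = [(0.55, 0.05, 0.05), (0.25, 1.0, 1.0),
               (0.14, 0.05, 10.0), (0.06, 1.0, 10.0)]
    recalls, false_rates = [], []
    for seed in (1, 2, 3):
        aln, truth = lv.simulate_alignment(
            lv.AlignmentRecipe(tree=fg_tree, n_codons=200, classes=classes),
            seed=seed)
        # true branch lengths: the check targets the empirical-Bayes site
        # classification, not branch-length estimation
        alt, _ = fit_nested_pair(aln, tree, "BS_A", foreground=fg,
                                 n_restarts=1)
        hits = site_posteriors(alt, aln, cutoff=0.80)
        found = {h.column for h in hits}
        true_sites = {i + 1 for i, c in enumerate(truth["site_classes"])
                      if c >= 2}
        recalls.append(len(found & true_sites) / len(true_sites))
        false_rates.append(len(found - true_sites) / max(len(found), 1))
    assert np.mean(recalls) >= 0.6
    assert np.mean(false_rates) <= 0.10


def test_site_posteriors_require_positive_class(small_tree, small_alignment):
    from longevol.models import fit_model
    tree, _ = estimate_branch_lengths(small_alignment, small_tree)
    fit = fit_model(small_alignment, tree, "M8A", n_restarts=1)
    with pytest.raises(SelectionInputError, match="not applicable"):
        site_posteriors(fit, small_alignment)


# -- root-to-tip omega --------------------------------------------------------

def _fake_free_fit(tree, rows):
    import pandas as pd
    from longevol.models import ModelFit
    return ModelFit(model="FREE_RATIO", lnl=0.0, kappa=2.0, params={},
                    classes=[], tree=tree, pi=np.ones(61) / 61,
                    x=np.zeros(1), converged=True, n_iter=1,
                    branch_table=pd.DataFrame(rows))


def test_root_to_tip_two_tip_example():
    tree = ArrayTree.from_newick("(A:0.3,B:0.3);", is_path=False)
    ia, ib = tree.tip_index("A"), tree.tip_index("B")
    rows = [{"node": ia, "label": "A", "t": 0.3, "omega": 0.5,
             "dn": 0.1, "ds": 0.2},
            {"node": ib, "label": "B", "t": 0.3, "omega": 0.0,
             "dn": 0.0, "ds": 0.3}]
    out = root_to_tip_omega(_fake_free_fit(tree, rows))
    assert out["A"] == pytest.approx(0.5)
    assert out["B"] == pytest.approx(0.0)


def test_root_to_tip_matches_brute_force_path_sums():
    tree = lv.simulate_tree(9, seed=77)
    rng = np.random.default_rng(4)
    rows = []
    dn = np.zeros(tree.n_nodes)
    ds = np.zeros(tree.n_nodes)
    for b in range(tree.n_nodes - 1):
        dn[b], ds[b] = rng.uniform(0, 0.1), rng.uniform(0.01, 0.2)
        rows.append({"node": b, "label": tree.labels[b] or "", "t": 0.1,
                     "omega": 1.0, "dn": dn[b], "ds": ds[b]})
    out = root_to_tip_omega(_fake_free_fit(tree, rows))
    for tip in tree.tip_indices:
        path = tree.path_to_root(tip)
        assert out[tree.labels[tip]] == pytest.approx(
            dn[path].sum() / ds[path].sum())
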