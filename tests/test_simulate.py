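"""The synthetic-data generator: determinism, truth records, calibration."""

import numpy as np
import pytest

import longevol as lv
from longevol.geneticcode import CODON_INDEX, N_CODONS, SENSE_CODONS
from longevol.likelihood import (
    PatternData,
    class_transition_tensor,
    mixture_loglik,
    prune_class_loglik,
)
from longevol.ratematrix import SpectralQ, build_rate_matrix, uniform_pi
from longevol.simulate import SimulationError
from longevol.trees import ArrayTree


def test_same_seed_same_alignment(small_tree):
    recipe = lv.AlignmentRecipe(tree=small_tree, n_codons=40)
    a1, t1 = lv.simulate_alignment(recipe, seed=12)
    a2, t2 = lv.simulate_alignment(recipe, seed=12)
    assert np.array_equal(a1.codons, a2.codons)
    assert t1 == t2
    a3, _ = lv.simulate_alignment(recipe, seed=13)
    assert not np.array_equal(a1.codons, a3.codons)


def test_omega_zero_forbids_nonsynonymous_events(small_tree):
    aln, truth = lv.simulate_alignment(
        lv.AlignmentRecipe(tree=small_tree, n_codons=60,
                           classes=[(1.0, 0.0, 0.0)]), seed=3)
    assert truth["n_nonsyn_events"] == 0
    assert truth["n_syn_events"] > 0
    aa = aln.translated()
    for col in range(aln.n_columns):  # realized columns conserve amino acid
        assert len(set(aa[:, col])) == 1


def test_zero_length_branches_copy_the_root():
    tree = ArrayTree.from_newick("(A:0.0,B:0.0,C:0.0);", is_path=False)
    aln, truth = lv.simulate_alignment(
        lv.AlignmentRecipe(tree=tree, n_codons=50), seed=8)
    assert (aln.codons == aln.codons[0]).all()
    assert truth["n_syn_events"] == truth["n_nonsyn_events"] == 0


def test_single_branch_transitions_match_matrix_exponential():
    """10^4 sites down one branch: empirical codon-pair frequencies agree
    with pi_i * P_ij within 3 binomial standard errors per cell."""
    tree = ArrayTree.from_newick("(A:0.5);", is_path=False)
    n = 10_000
    kappa, omega = 2.0, 0.5
    aln, truth = lv.simulate_alignment(
        lv.AlignmentRecipe(tree=tree, n_codons=n, kappa=kappa,
                           classes=[(1.0, omega, omega)]), seed=7)
    pi = uniform_pi()
    P = SpectralQ(build_rate_matrix(kappa, omega, pi), pi).probs(0.5)

    roots = np.array(truth["root_states"])
    tips = np.array([CODON_INDEX[c] for c in aln.codons[0]])
    counts = np.zeros((N_CODONS, N_CODONS))
    np.add.at(counts, (roots, tips), 1.0)
    n_from = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        emp = counts / n_from
    n_bad = n_cells = 0
    for i in range(N_CODONS):
        m = n_from[i, 0]
        if m < 30:
            continue
        se = np.sqrt(P[i] * (1 - P[i]) / m)
        # tolerance floored at one count: below that, agreement is not
        # measurable from m draws
        bad = np.abs(emp[i] - P[i]) > 3 * np.maximum(se, 1.0 / m)
        n_bad += bad.sum()
        n_cells += N_CODONS
    assert n_bad / n_cells < 0.01  # ~0.3% expected outside 3 SE


def test_trait_generator_calibration_fraction_flagged():
    """mean+1SD tail of the simulated LQ distribution across 20 seeds."""
    from longevol.traits import partition_cohort
    tree = lv.simulate_tree(48, seed=19)
    fractions = []
    for seed in range(20):
        traits = lv.simulate_traits(tree, seed=seed)
        part = partition_cohort(
            traits[["species", "mls_years", "bm_g"]]
            .itertuples(index=False, name=None))
        fractions.append(len(part.long_lived) / 48)
    assert 0.10 <= np.mean(fractions) <= 0.55


def test_trait_noise_lambda_one_recovered_by_pgls():
    """Strong phylogenetic signal planted in the lifespan noise should be
    picked up as a high lambda-hat in most replicates."""
    tree = lv.simulate_tree(32, seed=23)
    recipe = lv.TraitRecipe(noise_lambda=1.0)
    n_high = 0
    for seed in range(20):
        traits = lv.simulate_traits(tree, seed=seed, recipe=recipe)
        y = dict(zip(traits["species"], np.log10(traits["mls_years"])))
        x = dict(zip(traits["species"], np.log10(traits["bm_g"])))
        fit = lv.fit_pgls(y, x, tree)
        n_high += fit.lam >= 0.5
    assert n_high >= 16


def test_plant_convergence_round_trip(small_tree):
    from longevol.convergence import make_groups, scan
    aln, _ = lv.simulate_alignment(
        lv.AlignmentRecipe(tree=small_tree, n_codons=50,
                           classes=[(1.0, 0.1, 0.1)]), seed=2)
    species = aln.species
    carriers = [species[0], species[4]]
    planted = lv.plant_convergence(aln, 25, "W", carriers, seed=1)
    groups = make_groups({"a": [species[0]], "b": [species[4]]})
    controls = [s for s in species if s not in carriers]
    sites = scan(planted, groups, controls)
    assert any(s.column == 25 and s.residue == "W" for s in sites)


def test_plant_within_one_group_not_reported(small_tree):
    from longevol.convergence import make_groups, scan
    aln, _ = lv.simulate_alignment(
        lv.AlignmentRecipe(tree=small_tree, n_codons=50,
                           classes=[(1.0, 0.1, 0.1)]), seed=2)
    species = aln.species
    carriers = [species[0], species[1]]
    planted = lv.plant_convergence(aln, 10, "W", carriers, seed=1)
    groups = make_groups({"a": carriers, "b": [species[5]]})
    controls = [s for s in species if s not in carriers + [species[5]]]
    sites = scan(planted, groups, controls)
    assert not any(s.column == 10 for s in sites)


def test_plant_universal_residue_is_error(small_tree):
    aln, _ = lv.simulate_alignment(
        lv.AlignmentRecipe(tree=small_tree, n_codons=10,
                           classes=[(1.0, 0.0, 0.0)]), seed=2)
    col = 3
    res = aln.translated()[0, col - 1]
    with pytest.raises(SimulationError, match="universal"):
        lv.plant_convergence(aln, col, res, [aln.species[0]])


def test_generating_model_beats_misspecified_model_in_likelihood():
    """Identifiability sanity: the per-site lnL under the true omega exceeds
    the lnL with omega off by 4x, for every one of 10 seeds."""
    tree = lv.simulate_tree(8, seed=41, mean_root_to_tip=0.4)
    pi = uniform_pi()
    wins = 0
    for seed in range(10):
        aln, _ = lv.simulate_alignment(
            lv.AlignmentRecipe(tree=tree, n_codons=150,
                               classes=[(1.0, 0.2, 0.2)]), seed=seed)
        data = PatternData.from_alignment(aln, tree)
        lnls = []
        for om in (0.2, 0.8):
            P = class_transition_tensor(tree, 2.0, pi, [(1.0, om, om)])
            cl = prune_class_loglik(data, P, pi)
            total, _, _ = mixture_loglik(cl, [1.0], data.counts)
            lnls.append(total)
        wins += lnls[0] > lnls[1]
    assert wins == 10


def test_fixture_bundle_determinism_and_truth(tmp_path):
    b1 = lv.make_fixture_study(7, n_tips=8, n_codons=30)
    b2 = lv.make_fixture_study(7, n_tips=8, n_codons=30)
    d1, d2 = tmp_path / "b1", tmp_path / "b2"
    b1.write(d1)
    b2.write(d2)
    for f in sorted(d1.rglob("*")):
        if f.is_file():
            assert f.read_bytes() == (d2 / f.relative_to(d1)).read_bytes(), f
    assert set(b1.genes) == {"PSG1", "PSG2", "TRAITG", "CONVG",
                             "NULL1", "NULL2"}
    assert b1.truth["genes"]["CONVG"]["planted"] == "convergence"
    assert b1.truth["genes"]["NULL1"]["planted"] == "null"
    assert set(b1.truth["long_lived"]) <= set(b1.tree.tip_labels)


def test_bundle_passes_alignment_validation(tmp_path):
    from longevol.alignments import read_codon_fasta
    b = lv.make_fixture_study(3, n_tips=8, n_codons=30)
    d = b.write(tmp_path / "bundle")
    for fasta in sorted((d / "genes").glob("*.fasta")):
        aln = read_codon_fasta(fasta)
        assert aln.n_species == 8
        assert aln.n_columns == 30
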