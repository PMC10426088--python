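"""Synthetic data with the statistical structure the screen assumes.

Codon alignments are evolved along a rooted tree by event-level (Gillespie)
simulation under the same GY94 generators the likelihood engine uses, so
the generative model and the inference model agree exactly; the realised
substitution history (synonymous / nonsynonymous event counts, site-class
assignments) is recorded as truth.  Traits follow Brownian motion on log10
body mass, with log10 maximum lifespan coupled to body mass through an
exponent matching the longevity-quotient allometry plus phylogenetically
correlated noise, so the realised LQ distribution resembles a real mammal
cohort (mean about 1, sd about 0.6).  Convergent substitutions can be
planted at chosen columns for chosen carrier species.

One integer seed determines every stream: stage-level generators are
spawned from a single ``numpy.random.SeedSequence`` so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignments import CodonAlignment, write_codon_fasta
from .geneticcode import CODON_AA, GAP_CODON, SENSE_CODONS, encode_codon
from .ratematrix import floor_pi, mixture_scale, rate_matrix_unscaled, uniform_pi
from .trees import ArrayTree

ALLOMETRIC_LOG_COEF = np.log10(6.32)
ALLOMETRIC_EXP = 0.139


class SimulationError(ValueError):
    pass


# -- trees --------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, mean_root_to_tip: float = 0.3) -> ArrayTree:
    """Pure-birth tree with ``n_tips`` tips, scaled so the average
    root-to-tip path is ``mean_root_to_tip`` expected substitutions/codon."""
    from dendropy.model import birthdeath

    rng = random.Random(int(seed))
    taxa = dendropy.TaxonNamespace([f"Species_{i + 1:02d}" for i in range(n_tips)])
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=n_tips, rng=rng,
    )
    tree.is_rooted = True
    at = ArrayTree.from_dendropy(tree)
    depths = at.node_depths()
    mean_depth = float(np.mean(depths[at.tip_indices]))
    if mean_depth <= 0:
        raise SimulationError("degenerate simulated tree")
    lengths = at.branch_lengths * (mean_root_to_tip / mean_depth)
    # floor so sister tips are never exactly coincident (keeps V invertible)
    lengths[: at.root] = np.maximum(lengths[: at.root],
                                    1e-3 * mean_root_to_tip)
    return at.with_branch_lengths(lengths)


# -- codon alignments ---------------------------------------------------------

@dataclass
class AlignmentRecipe:
    """What to evolve: a tree, site classes (or per-branch omegas), kappa."""

    tree: ArrayTree
    n_codons: int
    kappa: float = 2.0
    classes: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(1.0, 0.2, 0.2)]
    )  # (weight, omega_background, omega_foreground)
    branch_omegas: np.ndarray | None = None  # free-ratio style, overrides classes
    pi: np.ndarray | None = None
    gene_id: str = "gene"


def _gillespie_branch(state: int, t: float, Q: np.ndarray, rng) -> tuple[int, int, int]:
    """Evolve one codon along one branch; returns (state, n_syn, n_nonsyn)."""
    n_syn = n_nonsyn = 0
    remaining = t
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            break
        wait = rng.exponential(1.0 / rate)
        if wait > remaining:
            break
        remaining -= wait
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        new = int(rng.choice(len(probs), p=probs))
        if CODON_AA[new] == CODON_AA[state]:
            n_syn += 1
        else:
            n_nonsyn += 1
        state = new
    return state, n_syn, n_nonsyn


def simulate_alignment(recipe: AlignmentRecipe, seed: int) -> tuple[CodonAlignment, dict]:
    """Evolve an alignment and return it with its truth record.

    Truth holds the per-site class assignment and the realised synonymous /
    nonsynonymous substitution counts; the same seed always yields the same
    alignment byte for byte.
    """
    if recipe.n_codons <= 0:
        raise SimulationError("n_codons must be positive")
    tree = recipe.tree
    pi = uniform_pi() if recipe.pi is None else floor_pi(recipe.pi)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))

    if recipe.branch_omegas is not None:
        omegas = np.asarray(recipe.branch_omegas, dtype=float)
        Q_by_node = {}
        for b in range(tree.n_nodes - 1):
            Q = rate_matrix_unscaled(recipe.kappa, float(omegas[b]), pi)
            r = float(-np.dot(pi, np.diag(Q)))
            Q_by_node[b] = Q / r
        site_classes = np.zeros(recipe.n_codons, dtype=int)

        def Q_for(node: int, cls: int) -> np.ndarray:
            return Q_by_node[node]
    else:
        weights = np.array([c[0] for c in recipe.classes])
        weights = weights / weights.sum()
        scale = mixture_scale(recipe.kappa, [c[1] for c in recipe.classes],
                              weights, pi)
        Q_bg, Q_fg = [], []
        for _, ob, of in recipe.classes:
            Q_bg.append(rate_matrix_unscaled(recipe.kappa, ob, pi) / scale)
            Q_fg.append(rate_matrix_unscaled(recipe.kappa, of, pi) / scale)
        site_classes = rng.choice(len(recipe.classes), size=recipe.n_codons,
                                  p=weights)

        def Q_for(node: int, cls: int) -> np.ndarray:
            return Q_fg[cls] if tree.foreground[node] else Q_bg[cls]

    root_states = rng.choice(len(SENSE_CODONS), size=recipe.n_codons, p=pi)
    states = np.zeros((tree.n_nodes, recipe.n_codons), dtype=int)
    states[tree.root] = root_states
    parents = tree.parents()
    n_syn = n_nonsyn = 0
    for node in reversed(range(tree.n_nodes - 1)):  # preorder
        t = float(tree.branch_lengths[node])
        par = parents[node]
        for s in range(recipe.n_codons):
            st, ks, kn = _gillespie_branch(int(states[par, s]), t,
                                           Q_for(node, int(site_classes[s])), rng)
            states[node, s] = st
            n_syn += ks
            n_nonsyn += kn

    tips = tree.tip_indices
    mat = np.empty((len(tips), recipe.n_codons), dtype="<U3")
    for i, tip in enumerate(tips):
        mat[i] = [SENSE_CODONS[k] for k in states[tip]]
    aln = CodonAlignment(recipe.gene_id, [tree.labels[t] for t in tips], mat)
    truth = {
        "gene": recipe.gene_id,
        "site_classes": site_classes.tolist(),
        "root_states": root_states.tolist(),
        "n_syn_events": int(n_syn),
        "n_nonsyn_events": int(n_nonsyn),
        "kappa": recipe.kappa,
    }
    return aln, truth


# -- traits -------------------------------------------------------------------

@dataclass
class TraitRecipe:
    """Brownian body mass plus allometric lifespan with lambda-structured noise.

    Defaults give a cohort whose LQ distribution is roughly lognormal with
    mean about 1 and sd about 0.6 — the shape of a broad mammal sample.
    """

    root_log10_bm: float = 3.5       # ~3 kg ancestor
    bm_sd: float = 1.5               # log10 grams across tips
    lifespan_exponent: float = ALLOMETRIC_EXP
    # intercept carries the lognormal mean correction -sigma^2/2 so E[LQ] = 1
    lifespan_intercept: float = ALLOMETRIC_LOG_COEF - 0.0968
    # marginal log10 sd chosen so the realised *sample* LQ sd of a related
    # cohort lands near 0.57 (phylogenetic correlation shrinks the sample sd
    # below the marginal value)
    noise_sd: float = 0.29
    noise_lambda: float = 0.5        # phylogenetic signal of the LQ noise


def simulate_traits(tree: ArrayTree, seed: int,
                    recipe: TraitRecipe | None = None) -> pd.DataFrame:
    """Trait table (species, mls_years, bm_g) with phylogenetic covariance."""
    recipe = recipe or TraitRecipe()
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    V, labels = tree.mrca_depth_matrix()
    scale = float(np.mean(np.diag(V)))
    if scale <= 0:
        raise SimulationError("tree has zero depth")
    Vn = V / scale
    nugget = 1e-8 * np.eye(len(labels))  # guards near-singular trees
    log_bm = recipe.root_log10_bm + rng.multivariate_normal(
        np.zeros(len(labels)), recipe.bm_sd**2 * Vn + nugget, method="cholesky")
    Vl = recipe.noise_lambda * Vn
    np.fill_diagonal(Vl, np.diag(Vn))
    noise = rng.multivariate_normal(
        np.zeros(len(labels)), recipe.noise_sd**2 * Vl + nugget,
        method="cholesky")
    log_mls = (recipe.lifespan_intercept
               + recipe.lifespan_exponent * log_bm + noise)
    return pd.DataFrame({
        "species": labels,
        "mls_years": 10.0**log_mls,
        "bm_g": 10.0**log_bm,
    })


# -- planted convergence ------------------------------------------------------

def plant_convergence(
    aln: CodonAlignment, column: int, residue: str, carriers, seed: int = 0
) -> CodonAlignment:
    """Force ``residue`` at 1-based ``column`` in every carrier and guarantee
    every non-carrier differs there.

    Carriers get the residue's codon closest (fewest base changes) to their
    current codon.  A non-carrier already holding the residue is resampled
    to a near-miss codon of a different amino acid; if the residue is
    universal this cannot be done meaningfully and is an error.
    """
    if not 1 <= column <= aln.n_columns:
        raise SimulationError(f"column {column} outside 1..{aln.n_columns}")
    carriers = set(carriers)
    missing = carriers - set(aln.species)
    if missing:
        raise SimulationError(f"carriers not in alignment: {sorted(missing)}")
    aa_col = [(_aa_of(cod) or "-") for cod in aln.codons[:, column - 1]]
    non_carrier_aas = {a for sp, a in zip(aln.species, aa_col)
                       if sp not in carriers and a not in ("-", "X")}
    if non_carrier_aas == {residue}:
        raise SimulationError(
            f"residue {residue} already universal outside the carrier set at "
            f"column {column}; cannot guarantee a control difference"
        )
    target_codons = [c for c, a in zip(SENSE_CODONS, CODON_AA) if a == residue]
    if not target_codons:
        raise SimulationError(f"{residue!r} is not an encodable amino acid")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    codons = aln.codons.copy()
    for i, sp in enumerate(aln.species):
        current = codons[i, column - 1]
        if sp in carriers:
            codons[i, column - 1] = _closest(current, target_codons)
        elif _aa_of(current) == residue:
            alternatives = [c for c, a in zip(SENSE_CODONS, CODON_AA)
                            if a != residue]
            dists = np.array([_hamming(current, c) for c in alternatives])
            best = [c for c, d in zip(alternatives, dists) if d == dists.min()]
            codons[i, column - 1] = best[int(rng.integers(len(best)))]
    return CodonAlignment(aln.gene_id, list(aln.species), codons)


def _aa_of(codon: str) -> str | None:
    k = encode_codon(codon)
    return CODON_AA[k] if k >= 0 else None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _closest(current: str, options: list[str]) -> str:
    if current == GAP_CODON or encode_codon(current) < 0:
        return options[0]
    dists = [_hamming(current, c) for c in options]
    return options[int(np.argmin(dists))]


def _plantable_site(aln: CodonAlignment, preferred_column: int) -> tuple[int, str]:
    """A (1-based column, residue) pair where the residue is absent from the
    column, searching outward from the preferred column."""
    aa = aln.translated()
    n = aln.n_columns
    for offset in range(n):
        for col in {max(preferred_column - offset, 1),
                    min(preferred_column + offset, n)}:
            present = set(aa[:, col - 1])
            for residue in "SWYHQNK":
                if residue not in present:
                    return col, residue
    raise SimulationError("no plantable column found")  # pragma: no cover


# -- full study bundle --------------------------------------------------------

@dataclass
class StudyBundle:
    tree: ArrayTree
    traits: pd.DataFrame
    genes: dict[str, CodonAlignment]
    domains: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        (out / "genes").mkdir(parents=True, exist_ok=True)
        with open(out / "tree.nwk", "w") as fh:
            fh.write(self.tree.to_newick() + "\n")
        # full float precision: a rounded trait table could flip a species
        # sitting at the LQ threshold relative to the recorded truth
        self.traits.to_csv(out / "traits.tsv", sep="\t", index=False,
                           float_format="%.17g")
        for name, aln in sorted(self.genes.items()):
            write_codon_fasta(aln, out / "genes" / f"{name}.fasta")
        self.domains.to_csv(out / "domains.tsv", sep="\t", index=False)
        groups = self.truth.get("groups", {})
        rows = [{"group": g, "species": s}
                for g, members in sorted(groups.items()) for s in members]
        pd.DataFrame(rows, columns=["group", "species"]).to_csv(
            out / "groups.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return out

    def pipeline_config(self, bundle_dir, **overrides):
        """A :class:`~longevol.pipeline.PipelineConfig` pointing at a written
        copy of this bundle."""
        from .pipeline import PipelineConfig

        bundle_dir = Path(bundle_dir)
        kwargs = dict(
            alignment_dir=str(bundle_dir / "genes"),
            tree_path=str(bundle_dir / "tree.nwk"),
            traits_path=str(bundle_dir / "traits.tsv"),
            domains_path=str(bundle_dir / "domains.tsv"),
            groups_path=str(bundle_dir / "groups.tsv"),
        )
        kwargs.update(overrides)
        return PipelineConfig(**kwargs)


def make_fixture_study(
    seed: int,
    n_tips: int = 48,
    n_codons: int = 120,
    foreground_omega: float = 6.0,
    foreground_fraction: float = 0.15,
) -> StudyBundle:
    """A complete synthetic study: tree, traits, six genes, domains, truth.

    Genes: two with positive selection on the long-lived terminal branches
    (branch-site-style mixture), one whose per-branch omega tracks the
    lifespan of descendant tips, one neutral-ish gene with a planted
    convergent column spanning two long-lived groups, and two purifying
    null genes.  The truth record states every planted signal.
    """
    from .traits import partition_cohort

    ss = np.random.SeedSequence(int(seed))
    tree_seed, trait_seed, *gene_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)
    ]
    tree = simulate_tree(n_tips, tree_seed)
    # draw trait tables until the mean+1SD rule flags at least two species
    # (needed for two convergence groups); deterministic in the seed
    for attempt in range(64):
        traits = simulate_traits(tree, (trait_seed + attempt) % (2**31))
        partition = partition_cohort(
            traits[["species", "mls_years", "bm_g"]]
            .itertuples(index=False, name=None))
        if len(partition.long_lived) >= 2:
            break
    else:  # pragma: no cover
        raise SimulationError("no trait draw yielded >= 2 long-lived species")
    long_lived = sorted(partition.long_lived)
    fg_tree = tree.with_foreground(long_lived)

    # two long-lived groups split by tree order, for the convergence plant
    tip_order = [l for l in tree.tip_labels if l in long_lived]
    half = max(len(tip_order) // 2, 1)
    groups = {"group_a": tip_order[:half], "group_b": tip_order[half:]}

    genes: dict[str, CodonAlignment] = {}
    truth_genes: dict[str, dict] = {}

    bs_classes = [
        (0.6, 0.15, 0.15), (0.25, 1.0, 1.0),
        (foreground_fraction * 0.7, 0.15, foreground_omega),
        (foreground_fraction * 0.3, 1.0, foreground_omega),
    ]
    for k, name in enumerate(["PSG1", "PSG2"]):
        aln, tr = simulate_alignment(
            AlignmentRecipe(tree=fg_tree, n_codons=n_codons, classes=bs_classes,
                            gene_id=name), gene_seeds[k])
        genes[name] = aln
        truth_genes[name] = {**tr, "planted": "foreground_selection"}

    # trait-coupled gene: branch omega follows mean log10 lifespan below it
    log_mls = dict(zip(traits["species"], np.log10(traits["mls_years"])))
    mean_mls = float(np.mean(list(log_mls.values())))
    desc: list[list[str]] = [[] for _ in range(tree.n_nodes)]
    for node in range(tree.n_nodes):
        if not tree.children[node]:
            desc[node] = [tree.labels[node]]
        else:
            desc[node] = [s for c in tree.children[node] for s in desc[c]]
    branch_omegas = np.array([
        float(np.clip(0.25 * 10 ** (0.8 * (np.mean([log_mls[s] for s in desc[b]])
                                           - mean_mls)), 0.02, 3.0))
        if b != tree.root else 0.25
        for b in range(tree.n_nodes)
    ])
    aln, tr = simulate_alignment(
        AlignmentRecipe(tree=tree, n_codons=n_codons,
                        branch_omegas=branch_omegas, gene_id="TRAITG"),
        gene_seeds[2])
    genes["TRAITG"] = aln
    truth_genes["TRAITG"] = {**tr, "planted": "trait_coupled_omega",
                             "branch_omegas": branch_omegas.tolist()}

    # convergence gene: purifying background + one planted column; the
    # residue is chosen absent from the column so the plant is well defined,
    # and carriers stay a minority so the cleaning majority rule keeps it
    per_group = 1 if n_tips < 16 else 2
    carriers = groups["group_a"][:per_group] + groups["group_b"][:per_group]
    aln, tr = simulate_alignment(
        AlignmentRecipe(tree=tree, n_codons=n_codons,
                        classes=[(1.0, 0.1, 0.1)], gene_id="CONVG"),
        gene_seeds[3])
    conv_col, conv_res = _plantable_site(aln, n_codons // 2)
    genes["CONVG"] = plant_convergence(aln, conv_col, conv_res, carriers,
                                       seed=gene_seeds[3])
    truth_genes["CONVG"] = {**tr, "planted": "convergence",
                            "column": conv_col, "residue": conv_res,
                            "carriers": carriers}

    for k, name in enumerate(["NULL1", "NULL2"]):
        aln, tr = simulate_alignment(
            AlignmentRecipe(tree=tree, n_codons=n_codons,
                            classes=[(1.0, 0.2, 0.2)], gene_id=name),
            gene_seeds[4 + k])
        genes[name] = aln
        truth_genes[name] = {**tr, "planted": "null"}

    domains = pd.DataFrame([
        {"gene": "CONVG", "domain": "planted_domain",
         "start": max(conv_col - 10, 1), "end": conv_col + 10},
        {"gene": "NULL1", "domain": "decoy_domain", "start": 1, "end": 10},
    ])
    truth = {
        "seed": int(seed),
        "n_tips": n_tips,
        "n_codons": n_codons,
        "long_lived": long_lived,
        "lq_threshold": partition.threshold,
        "groups": groups,
        "genes": truth_genes,
    }
    return StudyBundle(tree=tree, traits=traits, genes=genes,
                       domains=domains, truth=truth)
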