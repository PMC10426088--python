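"""Config-driven orchestration of the full longevity screen.

Stages, in order: trait partition -> alignment cleaning -> per-gene model
fits (branch-site and episodic tests per long-lived lineage, control-group
M8 vs M8a, free-ratio) -> FDR and the candidate rule -> root-to-tip omega
PGLS against MLS/BM/LQ -> convergent-site scan (with optional
expanded-panel verification) -> merged gene-class summary.  Every stage
writes a TSV into the result directory and appends a structured line to
``run_log.tsv``; the whole run is a pure function of (inputs, config,
seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .alignments import clean_alignment, map_to_reference, read_codon_fasta
from .convergence import (
    annotate_domains,
    make_groups,
    scan,
    sites_table,
    verify_expanded,
)
from .models import estimate_branch_lengths, fit_free_ratio, fit_nested_pair
from .pgls import regress_all
from .selection import (
    CONTROL_SITE_MODEL,
    SelectionTestResult,
    apply_fdr,
    candidate_genes,
    lrt,
    results_table,
    root_to_tip_omega,
    site_posteriors,
)
from .traits import partition_from_table, read_trait_table, write_partition
from .trees import ArrayTree

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    alignment_dir: str
    tree_path: str
    traits_path: str
    domains_path: str | None = None
    groups_path: str | None = None          # TSV: group <tab> species
    gene_lists: dict = field(default_factory=dict)  # label -> path of gene names
    expanded_alignment_dir: str | None = None
    expanded_traits_path: str | None = None
    alpha: float = 0.05
    fdr_scope: str = "method"               # method | global
    pp_cutoff: float = 0.80
    pp_strict: bool = True
    foreground_mode: str = "terminal"       # terminal | clades (groups file)
    max_gap_fraction: float = 0.0
    reference_species: str | None = None
    n_restarts: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise PipelineError(f"alpha must be in (0,1), got {self.alpha}")
        if self.fdr_scope not in ("method", "global"):
            raise PipelineError(f"bad fdr_scope {self.fdr_scope!r}")
        for label, p in [("alignment_dir", self.alignment_dir),
                         ("tree_path", self.tree_path),
                         ("traits_path", self.traits_path)]:
            if not Path(p).exists():
                raise PipelineError(f"{label} does not exist: {p}")
        if not sorted(Path(self.alignment_dir).glob("*.fasta")):
            raise PipelineError(f"no *.fasta files in {self.alignment_dir}")


def _read_groups(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"group", "species"}.issubset(df.columns):
        raise PipelineError("groups file needs columns: group, species")
    return {g: sorted(sub["species"]) for g, sub in df.groupby("group")}


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        with open(path, "w") as fh:
            fh.write("gene\tstage\twall_s\tstatus\n")

    def record(self, gene: str, stage: str, t0: float, status: str = "ok"):
        with open(self.path, "a") as fh:
            fh.write(f"{gene}\t{stage}\t{time.perf_counter() - t0:.2f}\t{status}\n")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the screen end to end; returns the result directory.

    Any stage failure halts with the stage and gene named; stage TSVs
    written before the failure are preserved.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.tsv")
    with open(out / "config_used.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)

    # -- traits & partition --------------------------------------------------
    t0 = time.perf_counter()
    traits = read_trait_table(config.traits_path)
    tree = ArrayTree.from_newick(config.tree_path)
    tree_species = set(tree.tip_labels)
    missing_traits = tree_species - set(traits["species"])
    if missing_traits:
        logger.warning("excluding %d tree species without traits from the "
                       "partition: %s", len(missing_traits), sorted(missing_traits))
    traits = traits[traits["species"].isin(tree_species)].reset_index(drop=True)
    partition = partition_from_table(traits)
    write_partition(partition, out / "partition.tsv")
    long_lived = sorted(partition.long_lived)
    controls = sorted(partition.control)
    log.record("-", "partition", t0)

    if config.groups_path:
        group_map = _read_groups(config.groups_path)
    else:
        group_map = {sp: [sp] for sp in long_lived}
    groups = make_groups(group_map, long_lived=set(long_lived))
    if config.foreground_mode == "terminal":
        lineages = [(sp, [sp]) for sp in long_lived]
    elif config.foreground_mode == "clades":
        lineages = [(g.group_id, sorted(g.members)) for g in groups]
    else:
        raise PipelineError(f"bad foreground_mode {config.foreground_mode!r}")

    # -- cleaning ------------------------------------------------------------
    gene_paths = sorted(Path(config.alignment_dir).glob("*.fasta"))
    alignments = {}
    clean_rows = []
    original_columns: dict[str, list[int]] = {}  # cleaned -> original 1-based
    for path in gene_paths:
        t0 = time.perf_counter()
        gene = path.stem
        aln = read_codon_fasta(path, gene_id=gene)
        extra = set(aln.species) - tree_species
        if extra:
            raise PipelineError(f"{gene}: species not in tree: {sorted(extra)}")
        cleaned, report = clean_alignment(aln, config.max_gap_fraction)
        alignments[gene] = cleaned
        original_columns[gene] = [
            col for a, b in report.kept_intervals for col in range(a, b + 1)
        ]
        for a, b in report.kept_intervals:
            clean_rows.append({"gene": gene, "kept_start": a, "kept_end": b})
        log.record(gene, "clean", t0)
    pd.DataFrame(clean_rows).to_csv(out / "cleaning.tsv", sep="\t", index=False)

    # -- per-gene selection machinery ----------------------------------------
    results: list[SelectionTestResult] = []
    omega_rows = {}
    fits_by_key = {}
    for gene, aln in sorted(alignments.items()):
        t0 = time.perf_counter()
        try:
            gene_tree, _ = estimate_branch_lengths(aln, tree)
        except Exception as exc:
            log.record(gene, "branch_lengths", t0, f"fail:{exc}")
            raise PipelineError(f"branch-length stage failed for {gene}: {exc}") from exc
        log.record(gene, "branch_lengths", t0)

        for lineage_id, fg in lineages:
            t0 = time.perf_counter()
            alt, null = fit_nested_pair(aln, gene_tree, "BS_A", foreground=fg,
                                        n_restarts=config.n_restarts)
            stat, p = lrt(alt.lnl, null.lnl, 1, boundary_mixture=True)
            results.append(SelectionTestResult(gene, lineage_id, "PAML_BS",
                                               stat, 1, p))
            fits_by_key[(gene, lineage_id, "PAML_BS")] = alt
            alt, null = fit_nested_pair(aln, gene_tree, "BUSTED_ALT",
                                        foreground=fg,
                                        n_restarts=config.n_restarts)
            stat, p = lrt(alt.lnl, null.lnl, 2)
            results.append(SelectionTestResult(gene, lineage_id, "BUSTED_LIKE",
                                               stat, 2, p))
            log.record(gene, f"branch_site:{lineage_id}", t0)

        # control-group site model on the control-only subtree
        t0 = time.perf_counter()
        control_aln = aln.subset(controls)
        control_tree = _prune_tree(gene_tree, controls)
        alt, null = fit_nested_pair(control_aln, control_tree, "M8",
                                    n_restarts=config.n_restarts)
        stat, p = lrt(alt.lnl, null.lnl, 1)
        ctrl = SelectionTestResult(gene, CONTROL_SITE_MODEL, "M8_VS_M8A",
                                   stat, 1, p)
        ctrl.significant = bool(p < config.alpha)
        ctrl.q = p
        results.append(ctrl)
        fits_by_key[(gene, CONTROL_SITE_MODEL, "M8_VS_M8A")] = (alt, control_aln)
        log.record(gene, "control_site_model", t0)

        t0 = time.perf_counter()
        free = fit_free_ratio(aln, gene_tree)
        omega_rows[gene] = root_to_tip_omega(free)
        log.record(gene, "free_ratio", t0)

    # -- FDR, sites, candidates ----------------------------------------------
    branch_results = [r for r in results if r.lineage != CONTROL_SITE_MODEL]
    apply_fdr(branch_results, alpha=config.alpha, scope=config.fdr_scope)
    for r in branch_results:
        if r.significant and r.method == "PAML_BS":
            fit = fits_by_key[(r.gene_id, r.lineage, "PAML_BS")]
            aln = alignments[r.gene_id]
            r.sites = site_posteriors(fit, aln, cutoff=config.pp_cutoff,
                                      strict=config.pp_strict)
            for s in r.sites:
                if config.reference_species in aln.species:
                    try:
                        s.reference_position = map_to_reference(
                            aln, config.reference_species, s.column)
                    except Exception:
                        pass
                # report sites in original (pre-cleaning) coordinates
                s.column = original_columns[r.gene_id][s.column - 1]
    results_table(results).to_csv(out / "selection.tsv", sep="\t", index=False)
    site_rows = [{"gene": r.gene_id, "lineage": r.lineage, "column": s.column,
                  "ref_pos": s.reference_position,
                  "posterior": round(s.posterior, 4)}
                 for r in results for s in r.sites]
    pd.DataFrame(site_rows, columns=["gene", "lineage", "column", "ref_pos",
                                     "posterior"]).to_csv(
        out / "selected_sites.tsv", sep="\t", index=False)

    reports = candidate_genes(results, alpha=config.alpha)
    pd.DataFrame([{
        "gene": r.gene_id, "candidate": int(r.candidate),
        "bs_lineages": ";".join(r.branch_site_lineages),
        "busted_lineages": ";".join(r.busted_lineages),
        "control_m8_significant": int(r.control_m8_significant),
    } for r in reports]).to_csv(out / "candidates.tsv", sep="\t", index=False)

    # -- PGLS ----------------------------------------------------------------
    t0 = time.perf_counter()
    omega_table = pd.DataFrame(omega_rows)
    omega_table.index.name = "species"
    omega_table.to_csv(out / "omega.tsv", sep="\t", float_format="%.6f")
    pgls_df = regress_all(omega_table, traits, tree, alpha=config.alpha)
    pgls_df.to_csv(out / "pgls.tsv", sep="\t", index=False, float_format="%.6f")
    log.record("-", "pgls", t0)

    # -- convergence ---------------------------------------------------------
    t0 = time.perf_counter()
    all_sites = []
    for gene, aln in sorted(alignments.items()):
        sites = scan(aln, groups, controls,
                     reference_species=config.reference_species)
        for s in sites:  # original (pre-cleaning) coordinates in reports
            s.column = original_columns[gene][s.column - 1]
        all_sites.extend(sites)
    if config.expanded_alignment_dir and config.expanded_traits_path:
        exp_traits = read_trait_table(config.expanded_traits_path)
        for gene in sorted({s.gene_id for s in all_sites}):
            path = Path(config.expanded_alignment_dir) / f"{gene}.fasta"
            if not path.exists():
                continue
            exp_aln = read_codon_fasta(path, gene_id=gene)
            gene_sites = [s for s in all_sites if s.gene_id == gene]
            verify_expanded(gene_sites, exp_aln, exp_traits,
                            partition.threshold, alignments[gene].species)
    if config.domains_path:
        domains = pd.read_csv(config.domains_path, sep="\t")
        annotate_domains(all_sites, domains)
    sites_table(all_sites).to_csv(out / "convergence.tsv", sep="\t", index=False)
    log.record("-", "convergence", t0)

    # -- summary -------------------------------------------------------------
    _write_summary(out, config)
    return out


def _prune_tree(tree: ArrayTree, keep_labels) -> ArrayTree:
    """Subtree induced by ``keep_labels``; suppressed internal branches have
    their lengths summed."""
    import dendropy

    dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                           preserve_underscores=True)
    dt.is_rooted = True
    dt.retain_taxa_with_labels(list(keep_labels))
    dt.suppress_unifurcations()
    return ArrayTree.from_dendropy(dt)


def _write_summary(out: Path, config: PipelineConfig) -> pd.DataFrame:
    df = summarize(out, gene_lists=config.gene_lists)
    df.to_csv(out / "summary.tsv", sep="\t", index=False)
    return df


def summarize(result_dir, gene_lists: dict | None = None) -> pd.DataFrame:
    """Union-of-evidence gene table from a completed run.

    One row per gene with boolean evidence-class columns (positively
    selected / longevity-associated / convergent) read straight from the
    stage files — nothing is recomputed — plus one boolean column per
    annotation list (e.g. cancer or aging gene sets).
    """
    result_dir = Path(result_dir)
    needed = ["candidates.tsv", "pgls.tsv", "convergence.tsv"]
    for name in needed:
        if not (result_dir / name).exists():
            raise PipelineError(f"missing stage output {name} in {result_dir}")
    candidates = pd.read_csv(result_dir / "candidates.tsv", sep="\t")
    pgls = pd.read_csv(result_dir / "pgls.tsv", sep="\t")
    conv = pd.read_csv(result_dir / "convergence.tsv", sep="\t")

    genes = sorted(set(candidates.get("gene", []))
                   | set(pgls.get("gene", [])) | set(conv.get("gene", [])))
    psg = set(candidates[candidates["candidate"] == 1]["gene"]) \
        if not candidates.empty else set()
    assoc = set(pgls[pgls["significant"]]["gene"]) \
        if not pgls.empty and "significant" in pgls else set()
    convergent = set(conv["gene"]) if not conv.empty else set()

    rows = []
    lists = {}
    for label, path in (gene_lists or {}).items():
        with open(path) as fh:
            lists[label] = {line.strip() for line in fh if line.strip()}
    for gene in genes:
        row = {
            "gene": gene,
            "positively_selected": int(gene in psg),
            "longevity_associated": int(gene in assoc),
            "convergent": int(gene in convergent),
        }
        row["any_evidence"] = int(bool(row["positively_selected"]
                                       or row["longevity_associated"]
                                       or row["convergent"]))
        for label, members in lists.items():
            row[label] = int(gene in members)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df.attrs["union_size"] = int(df["any_evidence"].sum())
    return df
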