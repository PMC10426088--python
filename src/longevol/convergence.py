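"""Convergent amino-acid site scanning across long-lived groups.

A column is convergent when some residue is carried by members of at least
two distinct long-lived groups (primates, bats, subterranean rodents,
cetaceans, ...) while every ungapped control species carries something
else.  Parallel and convergent origins are not distinguished (no ancestral
reconstruction): the criterion is the species-set difference the screening
tools of this field apply.  Candidate sites can then be re-examined on an
expanded species panel — any extra carrier must itself be long-lived by the
cohort's LQ threshold or the site is rejected — and placed in protein
domains supplied as reference-coordinate intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import pandas as pd

from .alignments import AlignmentError, CodonAlignment, map_to_reference
from .traits import compute_lq

MISSING = ("-", "X")


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class LongLivedGroup:
    group_id: str
    members: frozenset[str]


def make_groups(group_map: dict[str, list[str]], long_lived=None) -> list[LongLivedGroup]:
    """Build disjoint groups; every member must be long-lived if a partition
    is given."""
    seen: dict[str, str] = {}
    groups = []
    for gid, members in group_map.items():
        for m in members:
            if m in seen:
                raise ScanError(f"species {m!r} in groups {seen[m]!r} and {gid!r}")
            seen[m] = gid
            if long_lived is not None and m not in long_lived:
                raise ScanError(f"group member {m!r} is not long-lived")
        groups.append(LongLivedGroup(gid, frozenset(members)))
    return groups


@dataclass
class ConvergentSite:
    gene_id: str
    column: int                     # 1-based codon/residue column
    reference_position: int | None
    residue: str
    carriers: list[str]
    carrier_groups: list[str]
    control_residues: list[str]
    low_confidence: bool = False    # >50% of controls gapped at the column
    verified: bool | None = None    # None until expanded-panel verification
    extra_carriers: list[str] = field(default_factory=list)
    unassessable_carriers: list[str] = field(default_factory=list)
    domains: list[str] = field(default_factory=list)


def scan(
    aln: CodonAlignment,
    groups: list[LongLivedGroup],
    control_species,
    reference_species: str | None = None,
    require_all_members: bool = False,
) -> list[ConvergentSite]:
    """Report columns with a residue shared across >= 2 long-lived groups
    and absent from every ungapped control species.

    One carrier per group suffices by default; ``require_all_members``
    demands the residue be fixed within each carrying group.  Gapped
    controls are uninformative and do not veto, but a column where more
    than half the controls are gapped is flagged low-confidence.
    """
    aa = aln.translated()
    idx = {s: i for i, s in enumerate(aln.species)}
    controls = [s for s in control_species if s in idx]
    group_rows = [(g, [idx[m] for m in sorted(g.members) if m in idx])
                  for g in groups]
    sites = []
    for col in range(aln.n_columns):
        column = aa[:, col]
        ctrl_res = [column[idx[s]] for s in controls]
        informative = [r for r in ctrl_res if r not in MISSING]
        candidates: dict[str, list[tuple[str, list[str]]]] = {}
        for g, rows in group_rows:
            residues = [column[r] for r in rows]
            present = [r for r in residues if r not in MISSING]
            if not present:
                continue
            for res in set(present):
                if require_all_members and any(r != res for r in present):
                    continue
                members = [aln.species[r] for r in rows if column[r] == res]
                candidates.setdefault(res, []).append((g.group_id, members))
        for res, hits in sorted(candidates.items()):
            if len(hits) < 2:
                continue
            if any(r == res for r in informative):
                continue
            ref_pos = None
            if reference_species is not None:
                try:
                    ref_pos = map_to_reference(aln, reference_species, col + 1)
                except AlignmentError:
                    ref_pos = None
            carriers = sorted({m for _, ms in hits for m in ms})
            sites.append(ConvergentSite(
                gene_id=aln.gene_id, column=col + 1, reference_position=ref_pos,
                residue=res, carriers=carriers,
                carrier_groups=sorted(g for g, _ in hits),
                control_residues=sorted(set(informative)),
                low_confidence=len(informative) < 0.5 * max(len(controls), 1),
            ))
    return sites


def verify_expanded(
    sites: list[ConvergentSite],
    expanded_aln: CodonAlignment,
    expanded_traits: pd.DataFrame,
    lq_threshold: float,
    original_species,
) -> list[ConvergentSite]:
    """Check each site against an expanded species panel.

    Extra-panel species carrying the shared residue must all be long-lived
    (LQ above the cohort threshold, computed from the expanded trait
    table): one control-group carrier rejects the site; a carrier without
    trait data makes verification indeterminate (``verified=None``), never
    a silent pass.
    """
    aa = expanded_aln.translated()
    idx = {s: i for i, s in enumerate(expanded_aln.species)}
    original = set(original_species)
    tr = expanded_traits.set_index("species")
    for site in sites:
        extra = [s for s in expanded_aln.species
                 if s not in original and aa[idx[s], site.column - 1] == site.residue]
        site.extra_carriers = extra
        site.unassessable_carriers = [s for s in extra if s not in tr.index]
        assessable = [s for s in extra if s in tr.index]
        flags = [compute_lq(tr.loc[s, "mls_years"], tr.loc[s, "bm_g"]) > lq_threshold
                 for s in assessable]
        if site.unassessable_carriers:
            site.verified = None if all(flags) else False
        else:
            site.verified = all(flags)  # no extra carriers -> trivially True
    return sites


def annotate_domains(sites: list[ConvergentSite], domain_table: pd.DataFrame) -> list[ConvergentSite]:
    """Attach domain names whose [start, end] interval (1-based inclusive,
    reference protein coordinates) contains the site; overlaps all report."""
    required = {"gene", "domain", "start", "end"}
    if not required.issubset(domain_table.columns):
        raise ScanError(f"domain table needs columns {sorted(required)}")
    for site in sites:
        pos = site.reference_position
        if pos is None:
            continue
        rows = domain_table[domain_table["gene"] == site.gene_id]
        site.domains = sorted(
            str(r["domain"]) for _, r in rows.iterrows()
            if int(r["start"]) <= pos <= int(r["end"])
        )
    return sites


def sites_table(sites: list[ConvergentSite]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": s.gene_id, "column": s.column, "ref_pos": s.reference_position,
        "residue": s.residue, "carriers": ";".join(s.carriers),
        "groups": ";".join(s.carrier_groups),
        "verified": "" if s.verified is None else int(s.verified),
        "low_confidence": int(s.low_confidence),
        "domains": ";".join(s.domains),
    } for s in sites])
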