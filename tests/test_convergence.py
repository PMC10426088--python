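"""Convergent-site scanning, expanded-panel verification, domain placement."""

import numpy as np
import pandas as pd
import pytest

from longevol.alignments import CodonAlignment
from longevol.convergence import (
    ScanError,
    annotate_domains,
    make_groups,
    scan,
    sites_table,
    verify_expanded,
)
from longevol.geneticcode import CODON_AA, SENSE_CODONS

AA_TO_CODON = {}
for c, a in zip(SENSE_CODONS, CODON_AA):
    AA_TO_CODON.setdefault(a, c)


def aln_from_residues(columns_by_species: dict[str, str]) -> CodonAlignment:
    """Build a codon alignment whose translation equals the given strings."""
    species = list(columns_by_species)
    mat = np.array([
        ["---" if a == "-" else AA_TO_CODON[a] for a in columns_by_species[s]]
        for s in species
    ])
    return CodonAlignment("g", species, mat)


PRIMATES = ["Human", "Gorilla", "Chimp", "Bonobo"]
CONTROLS = ["Mouse", "Rat", "Cow"]


def sesn2_like_alignment():
    # column 2 carries S in four primates + the blind mole rat, T elsewhere
    rows = {sp: "MSK" for sp in PRIMATES}
    rows["BlindMoleRat"] = "MSK"
    rows.update({sp: "MTK" for sp in CONTROLS})
    return aln_from_residues(rows)


def test_scan_reports_shared_derived_residue_across_two_groups():
    aln = sesn2_like_alignment()
    groups = make_groups({"primates": PRIMATES, "bmr": ["BlindMoleRat"]})
    sites = scan(aln, groups, CONTROLS, reference_species="Human")
    assert len(sites) == 1
    (site,) = sites
    assert site.column == 2
    assert site.residue == "S"
    assert site.reference_position == 2
    assert set(site.carrier_groups) == {"primates", "bmr"}
    assert set(site.carriers) == set(PRIMATES) | {"BlindMoleRat"}
    assert site.control_residues == ["T"]


def test_scan_ignores_invariant_and_single_group_columns():
    aln = sesn2_like_alignment()
    groups = make_groups({"primates": PRIMATES})  # one group only
    assert scan(aln, groups, CONTROLS) == []
    rows = {sp: "MMM" for sp in PRIMATES + ["BlindMoleRat"] + CONTROLS}
    aln2 = aln_from_residues(rows)
    groups2 = make_groups({"primates": PRIMATES, "bmr": ["BlindMoleRat"]})
    assert scan(aln2, groups2, CONTROLS) == []


def test_scan_matches_exhaustive_set_logic_oracle():
    rng = np.random.default_rng(50)
    aas = [a for a in sorted(set(CODON_AA))]
    species = [f"L{i}" for i in range(6)] + [f"C{i}" for i in range(10)]
    group_map = {"g1": ["L0", "L1", "L2"], "g2": ["L3", "L4", "L5"]}
    controls = [f"C{i}" for i in range(10)]
    n_cols = 500
    mat = rng.choice(aas, size=(len(species), n_cols))
    # plant one unmistakable convergent column
    planted = 123
    mat[:, planted] = "T"
    for i, sp in enumerate(species):
        if sp in ("L0", "L4"):
            mat[i, planted] = "W"
    rows = {sp: "".join(mat[i]) for i, sp in enumerate(species)}
    aln = aln_from_residues(rows)
    groups = make_groups(group_map)
    sites = scan(aln, groups, controls)
    found = {(s.column, s.residue) for s in sites}

    expected = set()
    for col in range(n_cols):
        for res in set(mat[:, col]):
            in_g1 = any(mat[species.index(m), col] == res
                        for m in group_map["g1"])
            in_g2 = any(mat[species.index(m), col] == res
                        for m in group_map["g2"])
            ctrl_free = all(mat[species.index(c), col] != res
                            for c in controls)
            if in_g1 and in_g2 and ctrl_free:
                expected.add((col + 1, res))
    assert found == expected
    assert (planted + 1, "W") in found


def test_scan_stability_on_its_own_output():
    aln = sesn2_like_alignment()
    groups = make_groups({"primates": PRIMATES, "bmr": ["BlindMoleRat"]})
    sites = scan(aln, groups, CONTROLS)
    cols = [s.column - 1 for s in sites]
    sub = CodonAlignment("g", list(aln.species), aln.codons[:, cols])
    again = scan(sub, groups, CONTROLS)
    assert [(s.column, s.residue) for s in again] == \
        [(i + 1, s.residue) for i, s in enumerate(sites)]


def test_adding_a_carrier_control_removes_the_site():
    aln = sesn2_like_alignment()
    groups = make_groups({"primates": PRIMATES, "bmr": ["BlindMoleRat"]})
    assert len(scan(aln, groups, CONTROLS)) == 1
    # rebuild with one extra control that carries S at the site
    base = {sp: ("MSK" if sp in PRIMATES + ["BlindMoleRat"] else "MTK")
            for sp in aln.species}
    base["Koala"] = "MSK"
    aln2 = aln_from_residues(base)
    assert scan(aln2, groups, CONTROLS + ["Koala"]) == []


def test_gapped_controls_do_not_veto_but_flag_low_confidence():
    base = {sp: "MSK" for sp in PRIMATES + ["BlindMoleRat"]}
    base.update({"Mouse": "M-K", "Rat": "M-K", "Cow": "MTK"})
    aln = aln_from_residues(base)
    groups = make_groups({"primates": PRIMATES, "bmr": ["BlindMoleRat"]})
    sites = scan(aln, groups, ["Mouse", "Rat", "Cow"])
    (site,) = sites
    assert site.low_confidence  # 2 of 3 controls gapped


def test_groups_must_be_disjoint_and_long_lived():
    with pytest.raises(ScanError, match="groups"):
        make_groups({"a": ["X"], "b": ["X"]})
    with pytest.raises(ScanError, match="not long-lived"):
        make_groups({"a": ["X"]}, long_lived={"Y"})


def expanded_setup(extra_species, extra_residue, extra_traits):
    original = sesn2_like_alignment()
    groups = make_groups({"primates": PRIMATES, "bmr": ["BlindMoleRat"]})
    sites = scan(original, groups, CONTROLS)
    rows = {sp: ("MSK" if sp in PRIMATES + ["BlindMoleRat"] else "MTK")
            for sp in original.species}
    rows[extra_species] = extra_residue
    expanded = aln_from_residues(rows)
    traits = pd.DataFrame(
        [{"species": s, "mls_years": 20, "bm_g": 1000}
         for s in original.species] + extra_traits)
    return sites, expanded, traits, original


def test_verify_expanded_long_lived_extra_carrier_keeps_site():
    # extra carrier with bat-like traits: LQ = 3.9 >> threshold
    sites, expanded, traits, original = expanded_setup(
        "LittleBrownBat", "MSK",
        [{"species": "LittleBrownBat", "mls_years": 34, "bm_g": 10}])
    verify_expanded(sites, expanded, traits, lq_threshold=1.57,
                    original_species=original.species)
    assert sites[0].verified is True
    assert sites[0].extra_carriers == ["LittleBrownBat"]


def test_verify_expanded_control_like_extra_carrier_rejects_site():
    # koala-like carrier: LQ well below threshold
    sites, expanded, traits, original = expanded_setup(
        "Koala", "MSK", [{"species": "Koala", "mls_years": 22, "bm_g": 8500}])
    verify_expanded(sites, expanded, traits, lq_threshold=1.57,
                    original_species=original.species)
    assert sites[0].verified is False


def test_verify_expanded_no_extra_carriers_is_trivially_verified():
    sites, expanded, traits, original = expanded_setup(
        "Koala", "MTK", [{"species": "Koala", "mls_years": 22, "bm_g": 8500}])
    verify_expanded(sites, expanded, traits, lq_threshold=1.57,
                    original_species=original.species)
    assert sites[0].verified is True
    assert sites[0].extra_carriers == []


def test_verify_expanded_missing_traits_is_indeterminate():
    sites, expanded, traits, original = expanded_setup("Mystery", "MSK", [])
    verify_expanded(sites, expanded, traits, lq_threshold=1.57,
                    original_species=original.species)
    assert sites[0].verified is None
    assert sites[0].unassessable_carriers == ["Mystery"]


def test_annotate_domains_interval_membership():
    aln = sesn2_like_alignment()
    groups = make_groups({"primates": PRIMATES, "bmr": ["BlindMoleRat"]})
    sites = scan(aln, groups, CONTROLS, reference_species="Human")
    table = pd.DataFrame([
        {"gene": "g", "domain": "hit_dom", "start": 1, "end": 3},
        {"gene": "g", "domain": "miss_dom", "start": 5, "end": 9},
        {"gene": "other", "domain": "wrong_gene", "start": 1, "end": 9},
    ])
    annotate_domains(sites, table)
    assert sites[0].domains == ["hit_dom"]


def test_annotate_domains_matches_brute_force_on_random_intervals():
    rng = np.random.default_rng(9)
    aln = sesn2_like_alignment()
    groups = make_groups({"primates": PRIMATES, "bmr": ["BlindMoleRat"]})
    sites = scan(aln, groups, CONTROLS, reference_species="Human")
    pos = sites[0].reference_position
    rows = []
    for k in range(50):
        a = int(rng.integers(1, 10))
        b = int(rng.integers(a, 12))
        rows.append({"gene": "g", "domain": f"d{k}", "start": a, "end": b})
    table = pd.DataFrame(rows)
    annotate_domains(sites, table)
    expected = sorted(r["domain"] for r in rows
                      if r["start"] <= pos <= r["end"])
    assert sites[0].domains == expected


def test_sites_table_round_trip_columns():
    aln = sesn2_like_alignment()
    groups = make_groups({"primates": PRIMATES, "bmr": ["BlindMoleRat"]})
    df = sites_table(scan(aln, groups, CONTROLS, reference_species="Human"))
    assert list(df.columns) == ["gene", "column", "ref_pos", "residue",
                                "carriers", "groups", "verified",
                                "low_confidence", "domains"]
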