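"""Standard genetic code tables in the arrays the codon machinery needs.

Everything here is derived once, at import time, from Biopython's standard
codon table: the 61 sense codons in lexicographic (A<C<G<T) order, their
amino-acid translations, and the classification of every single-nucleotide
codon pair as transition/transversion and synonymous/nonsynonymous.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
GAP_CODON = "---"

_table = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

#: The 61 sense codons of the standard code, lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)

N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: codon index -> one-letter amino acid
CODON_AA: tuple[str, ...] = tuple(_table.forward_table[c] for c in SENSE_CODONS)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_AA)))  # 20

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-base change a<->b is a transition (pur<->pur or pyr<->pyr)."""
    return (a in _PURINES) == (b in _PURINES)


def _single_step_pairs():
    rows, cols, ts, syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            rows.append(i)
            cols.append(j)
            ts.append(is_transition(*diffs[0]))
            syn.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.array(rows, dtype=np.intp),
        np.array(cols, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


#: index arrays over all ordered single-nucleotide-step sense-codon pairs
STEP_I, STEP_J, STEP_IS_TRANSITION, STEP_IS_SYNONYMOUS = _single_step_pairs()


def translate_codon(codon: str) -> str:
    """Translate one codon cell: sense codon -> amino acid, '---' -> '-', else 'X'.

    Ambiguity codes and mixed-gap codons are masked as 'X' (missing), never
    silently dropped; stop codons also return 'X' since cleaned alignments
    may not contain internal stops.
    """
    codon = codon.upper()
    if codon == GAP_CODON:
        return "-"
    aa = _table.forward_table.get(codon)
    return aa if aa is not None else "X"


def encode_codon(codon: str) -> int:
    """Sense codon -> 0..60; anything else (gap, ambiguity, stop) -> -1 (missing)."""
    return CODON_INDEX.get(codon.upper(), -1)
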