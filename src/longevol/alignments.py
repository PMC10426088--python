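"""Codon alignment IO, cleaning and translation.

A codon alignment is an in-frame FASTA of equal-length nucleotide sequences.
On read it is columnised into an ``n_species x n_codon_columns`` matrix of
3-mers; a cell is either a full triplet or the full gap ``---`` (cells mixing
bases and gaps are gap-masked, with a warning).  Internal stop codons are a
frame error; a terminal stop column is trimmed.

Cleaning is a simplified block filter in the spirit of Gblocks run on codons
with no gaps allowed: a codon column is dropped when its gap fraction
exceeds ``max_gap_fraction`` (default 0) or when no amino acid is shared by
a strict majority of species.  The cleaning report records the retained
intervals in original 1-based codon coordinates so the filtering is
auditable; pre-cleaned alignments can equally be supplied as input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .geneticcode import GAP_CODON, STOP_CODONS, encode_codon, translate_codon

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    pass


class FrameError(AlignmentError):
    pass


class ReferenceGappedError(AlignmentError):
    """Raised when a column maps onto a gap in the reference sequence."""

    def __init__(self, species: str, column: int, nearest: int | None):
        self.species, self.column, self.nearest = species, column, nearest
        super().__init__(
            f"reference {species!r} is gapped at codon column {column}; "
            f"nearest ungapped reference position is {nearest}"
        )


@dataclass
class CodonAlignment:
    """Gap-aware in-frame codon matrix keyed by species."""

    gene_id: str
    species: list[str]
    codons: np.ndarray  # (n_species, n_columns) of 3-character strings

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype="<U3")
        if len(set(self.species)) != len(self.species):
            dup = sorted({s for s in self.species if self.species.count(s) > 1})
            raise AlignmentError(f"duplicate species in alignment: {dup}")
        if self.codons.shape[0] != len(self.species):
            raise AlignmentError("codon matrix rows do not match species list")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_columns(self) -> int:
        return self.codons.shape[1]

    def row(self, species: str) -> np.ndarray:
        try:
            return self.codons[self.species.index(species)]
        except ValueError:
            raise AlignmentError(f"species {species!r} not in alignment") from None

    def subset(self, keep_species) -> "CodonAlignment":
        keep = [s for s in self.species if s in set(keep_species)]
        idx = [self.species.index(s) for s in keep]
        return CodonAlignment(self.gene_id, keep, self.codons[idx])

    def encoded(self) -> np.ndarray:
        """Integer codon states, -1 for gap/ambiguous/stop (missing data)."""
        enc = np.vectorize(encode_codon, otypes=[int])
        return enc(self.codons)

    def translated(self) -> np.ndarray:
        """(n_species, n_columns) amino-acid matrix; '-' gaps, 'X' unresolvable."""
        tr = np.vectorize(translate_codon, otypes=["<U1"])
        aa = tr(self.codons)
        n_x = int(np.sum(aa == "X"))
        if n_x:
            logger.warning("%s: %d untranslatable codon cells masked as X",
                           self.gene_id, n_x)
        return aa


@dataclass
class CleaningReport:
    gene_id: str
    n_input_columns: int
    kept_intervals: list[tuple[int, int]]  # 1-based inclusive, original coords
    n_gap_removed: int
    n_nonconserved_removed: int

    @property
    def n_kept(self) -> int:
        return sum(b - a + 1 for a, b in self.kept_intervals)


def _mask_mixed_gap(codons: np.ndarray, gene_id: str) -> np.ndarray:
    mixed = np.vectorize(lambda c: ("-" in c) and c != GAP_CODON)(codons)
    if mixed.any():
        logger.warning("%s: %d mixed-gap codon cells masked to ---",
                       gene_id, int(mixed.sum()))
        codons = codons.copy()
        codons[mixed] = GAP_CODON
    return codons


def read_codon_fasta(path, gene_id: str | None = None) -> CodonAlignment:
    """Read an in-frame codon FASTA into a columnised alignment.

    Raises on ragged sequences, lengths not divisible by 3, duplicate
    headers, or internal stop codons; a final all-species stop column is
    trimmed silently (the usual state of CDS alignments).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise AlignmentError(f"duplicate FASTA header(s): {dup}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    (length,) = lengths
    if length % 3 != 0:
        raise FrameError(f"alignment length {length} not divisible by 3")
    n_col = length // 3
    mat = np.empty((len(records), n_col), dtype="<U3")
    for i, rec in enumerate(records):
        s = str(rec.seq).upper()
        mat[i] = [s[3 * k : 3 * k + 3] for k in range(n_col)]
    mat = _mask_mixed_gap(mat, gene_id or str(path))
    # trim a terminal stop column, then refuse internal stops
    if n_col and any(c in STOP_CODONS for c in mat[:, -1]):
        mat = mat[:, :-1]
        n_col -= 1
    stops = np.isin(mat, list(STOP_CODONS))
    if stops.any():
        i, j = np.argwhere(stops)[0]
        raise FrameError(
            f"internal stop codon {mat[i, j]} in {names[i]} at codon column {j + 1}"
        )
    return CodonAlignment(gene_id or str(path), names, mat)


def write_codon_fasta(aln: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=sp, description="")
        for sp, row in zip(aln.species, aln.codons)
    ]
    SeqIO.write(records, str(path), "fasta")


def column_is_conserved(aa_column: np.ndarray) -> bool:
    """Strict majority (>= 50% + 1) of species share the plurality amino acid.

    Gaps and X count toward the denominator but never as the plurality
    residue, so heavily gapped columns fail conservation too.
    """
    n = len(aa_column)
    residues, counts = np.unique(aa_column[~np.isin(aa_column, ["-", "X"])],
                                 return_counts=True)
    if len(counts) == 0:
        return False
    return int(counts.max()) >= n // 2 + 1


def clean_alignment(
    aln: CodonAlignment,
    max_gap_fraction: float = 0.0,
    min_block: int = 1,
) -> tuple[CodonAlignment, CleaningReport]:
    """Drop gappy and non-conserved codon columns; report retained intervals.

    ``min_block`` additionally drops retained runs shorter than the given
    number of consecutive columns (1 = pure per-column filtering).
    """
    gap_frac = np.mean(aln.codons == GAP_CODON, axis=0)
    aa = aln.translated()
    conserved = np.array([column_is_conserved(aa[:, j]) for j in range(aln.n_columns)])
    keep = (gap_frac <= max_gap_fraction + 1e-12) & conserved
    n_gap = int(np.sum(gap_frac > max_gap_fraction + 1e-12))
    n_noncons = int(np.sum(~conserved & (gap_frac <= max_gap_fraction + 1e-12)))
    if min_block > 1:
        keep = _drop_short_runs(keep, min_block)
    if not keep.any():
        raise AlignmentError(f"{aln.gene_id}: cleaning removed every column")
    intervals = _runs_to_intervals(keep)
    cleaned = CodonAlignment(aln.gene_id, list(aln.species), aln.codons[:, keep])
    report = CleaningReport(aln.gene_id, aln.n_columns, intervals, n_gap, n_noncons)
    return cleaned, report


def _drop_short_runs(keep: np.ndarray, min_block: int) -> np.ndarray:
    keep = keep.copy()
    start = None
    for j in range(len(keep) + 1):
        inside = j < len(keep) and keep[j]
        if inside and start is None:
            start = j
        elif not inside and start is not None:
            if j - start < min_block:
                keep[start:j] = False
            start = None
    return keep


def _runs_to_intervals(keep: np.ndarray) -> list[tuple[int, int]]:
    intervals, start = [], None
    for j in range(len(keep) + 1):
        inside = j < len(keep) and keep[j]
        if inside and start is None:
            start = j
        elif not inside and start is not None:
            intervals.append((start + 1, j))  # 1-based inclusive
            start = None
    return intervals


def map_to_reference(
    aln: CodonAlignment, reference_species: str, column: int
) -> int:
    """1-based position of 1-based codon ``column`` in the reference's
    ungapped protein sequence.

    Raises :class:`ReferenceGappedError` (carrying the nearest mappable
    position) if the reference itself is gapped at that column — the caller
    decides, never a silent shift.
    """
    if not 1 <= column <= aln.n_columns:
        raise AlignmentError(f"column {column} outside 1..{aln.n_columns}")
    row = aln.row(reference_species)
    gapped = row == GAP_CODON
    if gapped[column - 1]:
        ungapped_before = int(np.sum(~gapped[: column - 1]))
        nearest = ungapped_before if ungapped_before > 0 else (
            1 if (~gapped).any() else None
        )
        raise ReferenceGappedError(reference_species, column, nearest)
    return int(np.sum(~gapped[:column]))
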