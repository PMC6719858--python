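"""Bundled reference data: the canonical human SSBP1 sequence.

The precursor is 148 residues; the mature protein (after cleavage of the
mitochondrial targeting sequence) spans residues 17–148, and the
crystallographically ordered construct used for structural modelling
spans residues 26–140.  Numbering is that of the precursor, so the
disease substitution E27K sits at position 27.
"""

from __future__ import annotations

from importlib import resources

from Bio import SeqIO

__all__ = ["ssbp1_canonical_sequence", "ssbp1_construct_sequence", "load_fasta_sequence"]


def load_fasta_sequence(path) -> str:
    """First record of a FASTA file as an upper-case 1-letter string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def ssbp1_canonical_sequence() -> str:
    """Canonical human SSBP1 precursor sequence (148 aa)."""
    with resources.as_file(resources.files("ssbkit").joinpath("data/ssbp1_human.fasta")) as p:
        return load_fasta_sequence(p)


def ssbp1_construct_sequence(start: int = 26, end: int = 140) -> str:
    """Residues start..end (1-based, inclusive) of the canonical sequence."""
    seq = ssbp1_canonical_sequence()
    if not 1 <= start <= end <= len(seq):
        raise ValueError(f"range {start}..{end} outside 1..{len(seq)}")
    return seq[start - 1 : end]
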