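"""Shared sequence constants: amino-acid alphabet, background frequencies,
hydropathy scale, codon tables and small DNA helpers."""

from __future__ import annotations

import numpy as np

#: Canonical 20-residue alphabet, fixed index order used by all score matrices.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Robinson–Robinson style background residue frequencies (normalised to 1).
_RR = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.090, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064,
}
BACKGROUND_FREQUENCIES = np.array([_RR[aa] for aa in AMINO_ACIDS], dtype=float)
BACKGROUND_FREQUENCIES /= BACKGROUND_FREQUENCIES.sum()

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
KD_VECTOR = np.array([KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS], dtype=float)

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

#: One deterministic codon per residue (used for reverse translation of
#: synthetic proteins; every codon translates back under the standard code).
PREFERRED_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11]  # bacterial; standard aa assignments
    out = dict(table.forward_table)
    for stop in table.stop_codons:
        out[stop] = "*"
    return out


def codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        _CODON_TABLE.update(_build_codon_table())
    return _CODON_TABLE


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str, force_met_start: bool = False) -> str:
    """Translate an in-frame nucleotide string; stops render as ``*``.

    With ``force_met_start`` the first codon becomes M when it is a valid
    (possibly alternative) start codon, mirroring initiator-tRNA behaviour.
    """
    table = codon_table()
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aas.append(table.get(nt[i : i + 3].upper(), "X"))
    if force_met_start and aas and nt[:3].upper() in START_CODONS:
        aas[0] = "M"
    return "".join(aas)


def encode_protein(seq: str) -> np.ndarray:
    """Map a protein string to int8 indices; raises on unknown symbols."""
    try:
        return np.array([AA_INDEX[aa] for aa in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message formatting
        raise ValueError(f"unknown residue symbol: {exc.args[0]!r}") from None
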