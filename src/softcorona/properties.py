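"""Protein sequence physicochemistry: MW, pI, GRAVY, instability index.

Implements the four ProtParam-style parameters used to profile corona
composition, plus copy-number-weighted corona averages.

* Molecular weight: sum of average (isotope-abundance-weighted) residue
  masses plus one water.
* GRAVY: mean Kyte-Doolittle hydropathy over the residues.
* Instability index: Guruprasad's dipeptide-weight statistic,
  (10/L) * sum over adjacent dipeptides of DIWV values (values > 40
  suggest an unstable protein in vitro). The published 400-entry dipeptide
  table is taken from Biopython's ProtParam data.
* Isoelectric point: pH at which the Henderson-Hasselbalch net charge of
  the Bjellqvist ionizable groups (termini plus D, E, C, Y, H, K, R)
  crosses zero, found by bisection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import DIWV  # Guruprasad dipeptide weights

from .errors import EmptySampleError, InvalidSequenceError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Average residue (amino acid minus water) masses, Da.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Bjellqvist pKa set (the convention used by ExPASy ProtParam).
POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PK_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
                "V": 7.44, "E": 7.7}
PK_CTERMINAL = {"D": 4.55, "E": 4.75}


@dataclass(frozen=True)
class ProteinParameters:
    """The four sequence parameters of one protein."""

    mw: float  # Da
    pi: float  # pH units
    gravy: float  # dimensionless, Kyte-Doolittle bounds [-4.5, 4.5]
    instability: float  # dimensionless


def clean_sequence(sequence: str, skip_nonstandard: bool = False) -> str:
    """Validate and upper-case a sequence.

    Non-standard residues (B, Z, X, U, ...) raise by default; with
    ``skip_nonstandard`` they are dropped with a warning reporting the count
    — real FASTA inputs do contain them.
    """
    seq = str(sequence).strip().upper()
    if not seq:
        raise InvalidSequenceError("empty sequence")
    nonstd = [c for c in seq if c not in STANDARD_AA]
    if nonstd:
        if not skip_nonstandard:
            raise InvalidSequenceError(
                f"non-standard residue(s) {sorted(set(nonstd))} in sequence"
            )
        warnings.warn(
            f"skipped {len(nonstd)} non-standard residue(s) "
            f"({sorted(set(nonstd))})",
            stacklevel=2,
        )
        seq = "".join(c for c in seq if c in STANDARD_AA)
        if not seq:
            raise InvalidSequenceError("no standard residues left")
    return seq


def molecular_weight(sequence: str, skip_nonstandard: bool = False) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    seq = clean_sequence(sequence, skip_nonstandard)
    return sum(RESIDUE_MASS[c] for c in seq) + WATER_MASS


def gravy(sequence: str, skip_nonstandard: bool = False) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    seq = clean_sequence(sequence, skip_nonstandard)
    return sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)


def instability_index(sequence: str, skip_nonstandard: bool = False) -> float:
    """Guruprasad instability index, (10/L) * sum of dipeptide weights."""
    seq = clean_sequence(sequence, skip_nonstandard)
    if len(seq) < 2:
        raise InvalidSequenceError("instability index needs length >= 2")
    total = sum(DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 / len(seq) * total


def charge_at_ph(sequence: str, ph: float, skip_nonstandard: bool = False) -> float:
    """Net protein charge at a given pH (Bjellqvist pKa set).

    Positive groups contribute 1/(1 + 10^(pH - pKa)); negative groups
    contribute -1/(1 + 10^(pKa - pH)).
    """
    seq = clean_sequence(sequence, skip_nonstandard)
    pos = {"Nterm": PK_NTERMINAL.get(seq[0], POSITIVE_PKS["Nterm"])}
    neg = {"Cterm": PK_CTERMINAL.get(seq[-1], NEGATIVE_PKS["Cterm"])}
    charge = 0.0
    for group, pk in pos.items():
        charge += 1.0 / (1.0 + 10.0 ** (ph - pk))
    for aa in "KRH":
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - POSITIVE_PKS[aa]))
    for group, pk in neg.items():
        charge -= 1.0 / (1.0 + 10.0 ** (pk - ph))
    for aa in "DECY":
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (NEGATIVE_PKS[aa] - ph))
    return charge


def isoelectric_point(
    sequence: str, tol: float = 0.01, skip_nonstandard: bool = False
) -> float:
    """pH of zero net charge, by bisection on :func:`charge_at_ph`.

    The charge is strictly decreasing in pH, so bisection on [0, 14]
    converges; ``tol`` is the pH tolerance (default 0.01).
    """
    seq = clean_sequence(sequence, skip_nonstandard)
    lo, hi = 0.0, 14.0
    # charge(0) > 0 (protonated N-terminus), charge(14) < 0 (C-terminus)
    while hi - lo > tol / 2:
        mid = 0.5 * (lo + hi)
        if charge_at_ph(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_parameters(
    sequence: str, skip_nonstandard: bool = False
) -> ProteinParameters:
    """All four parameters of one sequence."""
    seq = clean_sequence(sequence, skip_nonstandard)
    return ProteinParameters(
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq),
        gravy=gravy(seq),
        instability=instability_index(seq),
    )


def parameters_table(
    sequences: Mapping[str, str], skip_nonstandard: bool = False
) -> pd.DataFrame:
    """Parameters for a set of accession -> sequence pairs."""
    rows = {
        acc: compute_parameters(seq, skip_nonstandard).__dict__
        for acc, seq in sequences.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["mw", "pi", "gravy", "instability"]
    ]


def number_weighted_average(
    params: pd.DataFrame, copies: Iterable[float]
) -> pd.Series:
    """Copy-number-weighted mean of each parameter over the corona.

    Weights are per-nanoparticle copy numbers; characterizes the "overall"
    physicochemical profile of the adsorbed layer.
    """
    w = np.asarray(list(copies), dtype=float)
    if len(w) != len(params):
        raise ValueError("copies and parameter table lengths differ")
    if np.any(w < 0):
        raise ValueError("copy numbers must be >= 0")
    total = w.sum()
    if total <= 0:
        raise EmptySampleError("all copy numbers are zero")
    return params.mul(w, axis=0).sum(axis=0) / total
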