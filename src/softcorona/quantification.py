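"""Absolute quantification of corona proteins per nanoparticle.

Converts label absorbances into degrees of labeling (DOL), and emPAI
relative-abundance tables plus bulk measurements (total adsorbed protein
mass by BCA, nanoparticle number concentration) into per-nanoparticle
protein masses and copy numbers:

    mass_i  = emPAI_i * Mw_i / sum_j(emPAI_j * Mw_j) * M_total
    copies_i = mass_i / Mw_i * N_A

with M_total the total corona protein mass carried by one nanoparticle.
The Avogadro constant defaults to 6.023e23 — the rounded convention used
when these copy numbers were introduced — so outputs are directly
comparable with published corona copy numbers; pass ``avogadro`` to
override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptySampleError,
    InvalidMeasurementError,
)

#: Rounded Avogadro constant (mol^-1) used for published corona copy numbers.
AVOGADRO = 6.023e23

#: Conventional sample labels of the four-control + capture design.
CONTROL_LABELS = ("HC", "HC-N3", "D Ctrl", "N3 Ctrl")
CAPTURED_LABEL = "HC+SC"


@dataclass(frozen=True)
class LabelingMeasurement:
    """UV absorbances and extinction coefficients of a labeled protein.

    Parameters
    ----------
    a_max : absorbance at the label's lambda_max (dimensionless)
    a_280 : absorbance at 280 nm
    eps_280 : protein molar extinction coefficient at 280 nm (M^-1 cm^-1)
    eps_max : label molar extinction coefficient at lambda_max (M^-1 cm^-1)
    cf : correction factor of the label at 280 nm (dimensionless)
    """

    a_max: float
    a_280: float
    eps_280: float
    eps_max: float
    cf: float = 0.0

    def __post_init__(self) -> None:
        if self.a_max < 0 or self.a_280 < 0:
            raise InvalidMeasurementError("absorbances must be non-negative")
        if self.eps_280 <= 0 or self.eps_max <= 0:
            raise InvalidMeasurementError("extinction coefficients must be > 0")
        if self.cf < 0:
            raise InvalidMeasurementError("correction factor must be >= 0")


@dataclass
class ProteinRecord:
    """One identified corona protein with its per-sample emPAI values."""

    accession: str
    mw: float  # Da
    empai: Mapping[str, float] = field(default_factory=dict)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise InvalidMeasurementError(
                f"{self.accession}: molecular weight must be > 0"
            )
        for label, value in self.empai.items():
            if not np.isfinite(value) or value < 0:
                raise InvalidMeasurementError(
                    f"{self.accession}: emPAI for {label!r} must be finite and >= 0"
                )


@dataclass(frozen=True)
class SampleMeasurement:
    """Bulk measurements for one corona sample.

    protein_mass_conc is the total corona protein mass concentration from
    the BCA assay in g ml^-1; np_number_conc is the nanoparticle number
    concentration in ml^-1. ``role`` is "control" or "captured" (the
    cross-linked HC+SC sample).
    """

    label: str
    protein_mass_conc: float  # g / ml
    np_number_conc: float  # 1 / ml
    role: str = "control"

    def __post_init__(self) -> None:
        if self.protein_mass_conc <= 0 or self.np_number_conc <= 0:
            raise InvalidMeasurementError(
                f"{self.label}: concentrations must be > 0"
            )
        if self.role not in ("control", "captured"):
            raise ConfigurationError(
                f"{self.label}: role must be 'control' or 'captured'"
            )


@dataclass
class CoronaMatrix:
    """Proteins x samples table of per-nanoparticle masses and copy numbers."""

    proteins: list  # accessions, ordered
    samples: list  # sample labels, ordered
    roles: list  # "control" | "captured", parallel to samples
    copies: np.ndarray  # proteins x samples, copies per NP
    masses: np.ndarray  # proteins x samples, g per NP
    mw: np.ndarray  # Da per protein
    m_total: np.ndarray  # g per NP per sample
    avogadro: float = AVOGADRO

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.roles) == "control")

    @property
    def captured_index(self) -> int:
        idx = np.flatnonzero(np.asarray(self.roles) == "captured")
        if idx.size != 1:
            raise ConfigurationError(
                f"expected exactly one captured sample, found {idx.size}"
            )
        return int(idx[0])

    def copies_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.copies, index=self.proteins, columns=self.samples)

    def masses_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.masses, index=self.proteins, columns=self.samples)

    def validate(self, rtol: float = 1e-9) -> None:
        """Check internal consistency: non-negativity, copies/masses link,
        and per-sample mass conservation against m_total."""
        if np.any(self.copies < 0) or np.any(self.masses < 0):
            raise InvalidMeasurementError("negative entries in corona matrix")
        expected = self.masses / self.mw[:, None] * self.avogadro
        if not np.allclose(self.copies, expected, rtol=1e-9, atol=0):
            raise InvalidMeasurementError("copies != masses/Mw * N_A")
        col = self.masses.sum(axis=0)
        if not np.allclose(col, self.m_total, rtol=rtol, atol=0):
            raise InvalidMeasurementError("column mass sums do not match M_total")


def compute_dol(m: LabelingMeasurement) -> float:
    """Degree of labeling: labels per protein from the conjugate UV spectrum.

    DOL = (A_max * eps_280) / ((A_280 - A_max * CF) * eps_max).
    """
    corrected = m.a_280 - m.a_max * m.cf
    if corrected <= 0:
        raise InvalidMeasurementError(
            "corrected protein absorbance (A_280 - A_max*CF) must be > 0, "
            f"got {corrected:g}"
        )
    return (m.a_max * m.eps_280) / (corrected * m.eps_max)


def total_mass_per_np(s: SampleMeasurement) -> float:
    """Total corona protein mass per nanoparticle, M_total (g/NP)."""
    return s.protein_mass_conc / s.np_number_conc


def mass_fractions(records: Sequence[ProteinRecord], sample: str) -> np.ndarray:
    """Per-protein contribution to the total adsorbed mass in one sample.

    fraction_i = emPAI_i * Mw_i / sum_j emPAI_j * Mw_j. Proteins with no
    emPAI entry for the sample contribute zero.
    """
    weights = np.array(
        [r.empai.get(sample, 0.0) * r.mw for r in records], dtype=float
    )
    total = weights.sum()
    if total <= 0:
        raise EmptySampleError(f"all emPAI values are zero in sample {sample!r}")
    return weights / total


def build_corona_matrix(
    records: Sequence[ProteinRecord],
    samples: Sequence[SampleMeasurement],
    avogadro: float = AVOGADRO,
) -> CoronaMatrix:
    """Assemble the proteins x samples copy-number matrix (Eq. mass/copies).

    Every sample label appearing in any record's emPAI map must have a
    matching :class:`SampleMeasurement`; absent emPAI entries count as zero.
    """
    labels = [s.label for s in samples]
    seen = set()
    for r in records:
        if r.accession in seen:
            raise ConfigurationError(f"duplicate accession {r.accession!r}")
        seen.add(r.accession)
        missing = set(r.empai) - set(labels)
        if missing:
            raise ConfigurationError(
                f"no sample measurement for label(s) {sorted(missing)}"
            )

    mw = np.array([r.mw for r in records], dtype=float)
    m_total = np.array([total_mass_per_np(s) for s in samples])
    masses = np.zeros((len(records), len(samples)))
    for j, s in enumerate(samples):
        fractions = mass_fractions(records, s.label)
        masses[:, j] = fractions * m_total[j]
    copies = masses / mw[:, None] * avogadro
    matrix = CoronaMatrix(
        proteins=[r.accession for r in records],
        samples=labels,
        roles=[s.role for s in samples],
        copies=copies,
        masses=masses,
        mw=mw,
        m_total=m_total,
        avogadro=avogadro,
    )
    matrix.validate()
    return matrix
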