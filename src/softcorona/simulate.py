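"""Synthetic corona experiments, protein sequences and SPR sensorgrams.

Emulates the study design every pipeline stage consumes, with known ground
truth:

* a corona proteome with log-normally distributed per-nanoparticle copy
  numbers, four low-variance hard-corona control samples and one captured
  (HC+SC) sample carrying planted soft-corona enrichment of three types
  plus "new" proteins absent from every control;
* random amino-acid sequences, optionally composition-biased to tune the
  expected GRAVY of a batch;
* multi-concentration Langmuir sensorgrams with configurable true binding
  sites, Gaussian noise and linear drift, plus the truth rasterized onto
  the fitting grid for recovery scoring.

Every generator is a pure function of its config (which carries the seed),
so outputs are byte-identical across runs. emPAI values are emitted on an
arbitrary positive per-sample scale — the quantification stage is invariant
to it — so recovered copy numbers round-trip to the planted values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quantification import (
    AVOGADRO,
    CAPTURED_LABEL,
    CONTROL_LABELS,
    CoronaMatrix,
    ProteinRecord,
    SampleMeasurement,
)
from .spr import InjectionSchedule, KineticGrid, Sensorgram, default_grid

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "IVLF"
HYDROPHILIC = "DEKRNQ"


@dataclass(frozen=True)
class CoronaSimConfig:
    """Design of one synthetic corona experiment.

    Defaults mirror the five-sample silica-nanoparticle study layout: 80
    identified proteins of which 20 are soft-corona (4 of them "new",
    i.e. undetected in all controls), copy numbers log-normal with median
    5 copies/NP and sigma_log 1 (so a typical particle carries a few
    hundred protein copies in total), 10% multiplicative control noise,
    and per-type soft/hard gain bands consistent with the type-1/2/3
    classification rule at similarity ratio 1.5.
    """

    n_proteins: int = 80
    n_sc_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"type1": 5, "type2": 5, "type3": 6, "new": 4}
    )
    copy_median: float = 5.0
    sigma_log: float = 1.0
    control_noise_cv: float = 0.1
    soft_gain: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "type1": (0.2, 0.5),
            "type2": (0.8, 1.25),
            "type3": (2.5, 6.0),
        }
    )
    mw_median: float = 50_000.0
    mw_sigma_log: float = 0.6
    np_number_conc: float = 1e12  # particles per ml
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(self.n_sc_per_type)
        if any(v < 0 for v in counts.values()):
            raise ConfigurationError("SC type counts must be >= 0")
        if sum(counts.values()) > self.n_proteins:
            raise ConfigurationError("more SC proteins than proteins")
        if self.control_noise_cv < 0:
            raise ConfigurationError("control_noise_cv must be >= 0")


@dataclass
class CoronaExperiment:
    """Generated experiment: pipeline inputs plus ground truth."""

    records: list  # ProteinRecord with per-sample emPAI
    samples: list  # SampleMeasurement, 4 controls + captured
    truth: pd.DataFrame  # per-protein planted labels and copies
    matrix: CoronaMatrix  # the planted copy-number matrix


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=size)


def generate_corona_experiment(cfg: CoronaSimConfig) -> CoronaExperiment:
    """Draw one corona proteome with planted HC/SC structure.

    Controls are hard-state copies with multiplicative noise; the captured
    sample carries hard + planted soft copies (per-type soft/hard gain).
    emPAI values are derived from the realized masses so that the
    quantification stage reproduces the planted copy numbers exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    counts = {t: cfg.n_sc_per_type.get(t, 0) for t in ("type1", "type2", "type3", "new")}

    types = np.array(
        sum(([t] * c for t, c in counts.items()), [])
        + ["hc"] * (n - sum(counts.values()))
    )
    rng.shuffle(types)
    accessions = [f"SYN{i:04d}" for i in range(n)]

    mw = rng.lognormal(np.log(cfg.mw_median), cfg.mw_sigma_log, n)
    hard = rng.lognormal(np.log(cfg.copy_median), cfg.sigma_log, n)
    hard[types == "new"] = 0.0

    gain = np.zeros(n)
    for t, (lo, hi) in cfg.soft_gain.items():
        sel = types == t
        gain[sel] = rng.uniform(lo, hi, sel.sum())

    n_controls = len(CONTROL_LABELS)
    controls = hard[:, None] * _lognormal_noise(
        rng, cfg.control_noise_cv, (n, n_controls)
    )
    captured = hard * (1.0 + gain) * _lognormal_noise(rng, cfg.control_noise_cv, n)
    new_sel = types == "new"
    captured[new_sel] = rng.lognormal(
        np.log(cfg.copy_median), cfg.sigma_log, new_sel.sum()
    )

    copies = np.column_stack([controls, captured])
    labels = list(CONTROL_LABELS) + [CAPTURED_LABEL]
    roles = ["control"] * n_controls + ["captured"]

    masses = copies * mw[:, None] / AVOGADRO
    m_total = masses.sum(axis=0)
    # emPAI on an arbitrary positive per-sample scale: emPAI_i ~ mass_i / Mw_i
    scales = rng.uniform(0.5, 50.0, len(labels))
    records = []
    for i, acc in enumerate(accessions):
        empai = {
            lab: float(masses[i, j] / mw[i] * scales[j] / m_total[j] * 1e6)
            for j, lab in enumerate(labels)
        }
        records.append(ProteinRecord(accession=acc, mw=float(mw[i]), empai=empai))

    samples = [
        SampleMeasurement(
            label=lab,
            protein_mass_conc=float(m_total[j] * cfg.np_number_conc),
            np_number_conc=cfg.np_number_conc,
            role=role,
        )
        for j, (lab, role) in enumerate(zip(labels, roles))
    ]

    matrix = CoronaMatrix(
        proteins=accessions,
        samples=labels,
        roles=roles,
        copies=copies,
        masses=masses,
        mw=mw,
        m_total=m_total,
    )

    cmax = controls.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = np.where(cmax > 0, captured / np.where(cmax > 0, cmax, 1.0), np.inf)
    truth = pd.DataFrame(
        {
            "accession": accessions,
            "is_sc": types != "hc",
            "sc_type": np.where(types == "hc", "not_applicable", types),
            "hard_base": hard,
            "soft_gain": gain,
            "captured_copies": captured,
            "realized_enrichment": enrichment,
        }
    ).set_index("accession")
    return CoronaExperiment(records=records, samples=samples, truth=truth,
                            matrix=matrix)


def generate_sequences(
    n: int,
    length_range: tuple = (120, 600),
    seed: int = 0,
    bias: Optional[str] = None,
    accessions: Optional[Sequence[str]] = None,
) -> dict:
    """Random protein sequences over the 20 standard amino acids.

    ``bias`` of "hydrophobic" (I/V/L/F weighted 4x) or "hydrophilic"
    (D/E/K/R/N/Q weighted 4x) shifts the expected GRAVY of the batch up or
    down; ``None`` draws uniformly.
    """
    if n < 1:
        raise ConfigurationError("need n >= 1")
    rng = np.random.default_rng(seed)
    weights = np.ones(len(STANDARD_AA))
    boost = {"hydrophobic": HYDROPHOBIC, "hydrophilic": HYDROPHILIC}.get(bias, "")
    if bias is not None and not boost:
        raise ConfigurationError(f"unknown bias {bias!r}")
    for c in boost:
        weights[STANDARD_AA.index(c)] = 4.0
    weights = weights / weights.sum()
    if accessions is None:
        accessions = [f"SYN{i:04d}" for i in range(n)]
    aa = np.array(list(STANDARD_AA))
    out = {}
    for acc in accessions:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        out[acc] = "".join(rng.choice(aa, size=length, p=weights))
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    """Write accession -> sequence pairs as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


@dataclass(frozen=True)
class SprSimConfig:
    """True binding sites and acquisition settings for sensorgram synthesis.

    Default schedule follows the published sequential-injection layout
    (20-3000 nM, 800 s association, dissociation to 2400 s); the default
    two-site truth has a high-affinity minor site and a weak fast-off major
    site at a 70:30 amplitude split.
    """

    true_sites: tuple = ((1e-7, 1e-3, 70.0), (1e-4, 1e-1, 30.0))
    schedule: InjectionSchedule = field(default_factory=InjectionSchedule)
    noise_sigma: float = 1.0  # RU
    drift_slope: float = 0.0  # RU / s
    dt: float = 1.0  # s sampling interval (Biacore-class acquisition ~1 Hz)
    mode: str = "independent_cycles"
    seed: int = 0

    def __post_init__(self) -> None:
        for kd, koff, amp in self.true_sites:
            if kd <= 0 or koff <= 0:
                raise ConfigurationError("site K_D and k_off must be > 0")
            if amp < 0:
                raise ConfigurationError("site amplitudes must be >= 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")


def rasterize_truth(
    sites: Sequence[tuple], grid: Optional[KineticGrid] = None
) -> KineticGrid:
    """Place each true site's amplitude on its nearest grid node (log space)."""
    if grid is None:
        grid = default_grid()
    weights = np.zeros((len(grid.kd_values), len(grid.koff_values)))
    for kd, koff, amp in sites:
        i = int(np.argmin(np.abs(np.log10(grid.kd_values) - np.log10(kd))))
        j = int(np.argmin(np.abs(np.log10(grid.koff_values) - np.log10(koff))))
        weights[i, j] += amp
    return KineticGrid(
        kd_values=grid.kd_values, koff_values=grid.koff_values, weights=weights
    )


def generate_sensorgrams(cfg: SprSimConfig) -> tuple[Sensorgram, KineticGrid]:
    """Noisy multi-concentration Langmuir sensorgram plus rasterized truth.

    R(t) = sum_sites amplitude * theta(t) + drift_slope * t + N(0, sigma^2),
    sampled every ``dt`` seconds over each full cycle.
    """
    from .spr import _theta_cycles  # shared closed-form basis

    rng = np.random.default_rng(cfg.seed)
    sched = cfg.schedule
    times = np.arange(0.0, sched.t_dissoc_end + cfg.dt / 2, cfg.dt)
    kd = np.array([s[0] for s in cfg.true_sites])
    koff = np.array([s[1] for s in cfg.true_sites])
    amps = np.array([s[2] for s in cfg.true_sites])
    blocks = _theta_cycles(kd, koff, sched, [times] * sched.n_cycles, cfg.mode)

    all_t, all_r, all_c = [], [], []
    for c, theta in enumerate(blocks):
        resp = amps @ theta + cfg.drift_slope * times
        if cfg.noise_sigma > 0:
            resp = resp + rng.normal(0.0, cfg.noise_sigma, len(times))
        all_t.append(times)
        all_r.append(resp)
        all_c.append(np.full(len(times), c))
    sensorgram = Sensorgram(
        time=np.concatenate(all_t),
        response=np.concatenate(all_r),
        cycle=np.concatenate(all_c),
    )
    return sensorgram, rasterize_truth(cfg.true_sites)
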