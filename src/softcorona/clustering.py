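"""Soft-corona identification and classification from copy-number matrices.

The cross-linked HC+SC sample is compared against four hard-corona control
preparations. A protein belongs to the soft-corona (SC) cluster when its
per-nanoparticle copy number is consistently lower in *all* controls — by at
least an enrichment factor relative to the highest control, and without
large variation among the controls (otherwise the apparent enrichment could
be random). SC proteins are then split into three types by comparing copies
in the hard binding state (mean of the controls) with copies in the soft
state (capture excess):

* type 1 — more copies bound hard (hard/soft > ratio),
* type 2 — similar copies in both states,
* type 3 — more copies bound soft (soft/hard > ratio),
* new    — undetected in every control, appearing only after capture.

Heatmap analytics mirror the published workflow: square-root transform,
per-protein z-scaling, and two-way Ward/Euclidean hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidInputError,
)
from .quantification import CoronaMatrix

DEFAULT_ENRICHMENT_FACTOR = 1.5
DEFAULT_MAX_CONTROL_CV = 0.5
DEFAULT_SIMILARITY_RATIO = 1.5

SC_TYPES = ("type1", "type2", "type3", "new")


@dataclass
class ClusteringResult:
    """Two-way Ward/Euclidean dendrograms over the scaled matrix."""

    row_linkage: np.ndarray
    column_linkage: np.ndarray
    row_order: np.ndarray
    column_order: np.ndarray
    zmatrix: np.ndarray
    zero_variance_rows: np.ndarray  # boolean mask over proteins


def transform_and_scale(m: CoronaMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Square-root transform, then z-score each protein row (ddof=1).

    Rows with zero variance after the transform are set to all-zeros and
    flagged (second return value, boolean per protein).
    """
    if m.copies.shape[1] < 2:
        raise InsufficientDataError("need >= 2 samples to scale rows")
    root = np.sqrt(m.copies)
    mean = root.mean(axis=1, keepdims=True)
    sd = root.std(axis=1, ddof=1, keepdims=True)
    zero_var = (sd[:, 0] == 0)
    sd[zero_var] = 1.0
    z = (root - mean) / sd
    z[zero_var] = 0.0
    return z, zero_var


def hierarchical_two_way(zmatrix: np.ndarray) -> ClusteringResult:
    """Ward's minimum-variance linkage on Euclidean distances, rows and
    columns; leaf orders from scipy's deterministic dendrogram ordering."""
    z = np.asarray(zmatrix, dtype=float)
    if not np.all(np.isfinite(z)):
        raise InvalidInputError("scaled matrix contains non-finite values")
    zero_var = np.zeros(z.shape[0], dtype=bool)
    row_linkage = hierarchy.linkage(z, method="ward", metric="euclidean")
    column_linkage = hierarchy.linkage(z.T, method="ward", metric="euclidean")
    return ClusteringResult(
        row_linkage=row_linkage,
        column_linkage=column_linkage,
        row_order=hierarchy.leaves_list(row_linkage),
        column_order=hierarchy.leaves_list(column_linkage),
        zmatrix=z,
        zero_variance_rows=zero_var,
    )


def _control_stats(m: CoronaMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, max, CV) of copies over the control columns, per protein.

    CV uses the sample standard deviation (ddof=1); proteins whose control
    mean is zero get CV = 0 (the all-zero case is handled separately)."""
    ctrl = m.copies[:, m.control_indices]
    mean = ctrl.mean(axis=1)
    cmax = ctrl.max(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    cv = np.zeros_like(mean)
    pos = mean > 0
    cv[pos] = sd[pos] / mean[pos]
    return mean, cmax, cv


def identify_sc_cluster(
    m: CoronaMatrix,
    enrichment_factor: float = DEFAULT_ENRICHMENT_FACTOR,
    max_control_cv: float = DEFAULT_MAX_CONTROL_CV,
) -> Set[str]:
    """Rule-based SC set: enrichment over every control, consistent controls.

    A protein is SC iff copies(captured) >= enrichment_factor * max(control
    copies) AND its control coefficient of variation <= max_control_cv (or
    all controls are exactly zero, in which case any positive capture makes
    it a "new" SC protein).
    """
    if enrichment_factor < 1:
        raise ConfigurationError("enrichment_factor must be >= 1")
    if max_control_cv <= 0:
        raise ConfigurationError("max_control_cv must be > 0")
    if len(m.control_indices) < 2:
        raise ConfigurationError("need >= 2 control samples")
    captured = m.copies[:, m.captured_index]
    _, cmax, cv = _control_stats(m)

    all_zero = cmax == 0
    enriched = captured >= enrichment_factor * cmax
    consistent = cv <= max_control_cv
    is_sc = np.where(
        all_zero,
        captured > 0,
        enriched & consistent & (captured > 0),
    )
    return {m.proteins[i] for i in np.flatnonzero(is_sc)}


def classify_sc_types(
    m: CoronaMatrix,
    sc_set: Set[str],
    similarity_ratio: float = DEFAULT_SIMILARITY_RATIO,
) -> pd.DataFrame:
    """Per-protein classification table.

    hard_copies is the mean over the four control columns; soft_copies is
    the capture excess, floored at zero. SC proteins split into type1/2/3
    by the hard/soft copy ratio against ``similarity_ratio``; proteins with
    zero hard copies are "new". Columns: cluster, sc_type, hard_copies,
    soft_copies, fold_increase (NaN where controls are zero), control_cv.
    """
    if similarity_ratio <= 1:
        raise ConfigurationError("similarity_ratio must be > 1")
    unknown = sc_set - set(m.proteins)
    if unknown:
        raise ConfigurationError(f"SC accessions not in matrix: {sorted(unknown)}")
    captured = m.copies[:, m.captured_index]
    hard, _, cv = _control_stats(m)
    soft = np.maximum(0.0, captured - hard)

    rows = []
    for i, acc in enumerate(m.proteins):
        in_sc = acc in sc_set
        if not in_sc:
            sc_type = "not_applicable"
        elif hard[i] == 0:
            sc_type = "new"
        elif soft[i] == 0 or hard[i] / soft[i] > similarity_ratio:
            sc_type = "type1"
        elif soft[i] / hard[i] > similarity_ratio:
            sc_type = "type3"
        else:
            sc_type = "type2"
        fold = captured[i] / hard[i] if hard[i] > 0 else np.nan
        rows.append(
            {
                "accession": acc,
                "cluster": "SC" if in_sc else "HC",
                "sc_type": sc_type,
                "hard_copies": hard[i],
                "soft_copies": soft[i],
                "fold_increase": fold,
                "control_cv": cv[i],
            }
        )
    return pd.DataFrame(rows).set_index("accession")


def fold_increase(m: CoronaMatrix) -> pd.Series:
    """Capture-to-control abundance ratio per protein.

    Returns captured copies / mean(control copies); "New" where controls
    are all zero but capture is positive; NaN where both are zero.
    """
    captured = m.copies[:, m.captured_index]
    hard, _, _ = _control_stats(m)
    out = []
    for cap, h in zip(captured, hard):
        if h > 0:
            out.append(cap / h)
        elif cap > 0:
            out.append("New")
        else:
            out.append(np.nan)
    return pd.Series(out, index=m.proteins, name="fold_increase")


def composition_summary(
    m: CoronaMatrix, classification: pd.DataFrame
) -> dict:
    """HC/SC-cluster copy totals and per-protein number percentages.

    Reported for the averaged controls ("control") and the captured sample
    ("captured"): total copies per cluster, the cluster's share of the
    total, and each protein's number percentage within the role.
    """
    clusters = classification.loc[m.proteins, "cluster"].to_numpy()
    control_mean = m.copies[:, m.control_indices].mean(axis=1)
    captured = m.copies[:, m.captured_index]
    roles = {"control": control_mean, "captured": captured}

    totals = {}
    percentages = {}
    for role, copies in roles.items():
        total = copies.sum()
        totals[role] = {
            "HC": copies[clusters == "HC"].sum(),
            "SC": copies[clusters == "SC"].sum(),
            "total": total,
        }
        percentages[role] = 100.0 * copies / total if total > 0 else copies * 0.0
    totals_df = pd.DataFrame(totals)
    pct_df = pd.DataFrame(percentages, index=m.proteins)
    return {"totals": totals_df, "percentages": pct_df}


def best_dendrogram_cut(
    result: ClusteringResult,
    proteins: Sequence[str],
    sc_set: Set[str],
    max_clusters: Optional[int] = None,
) -> dict:
    """Dendrogram cut whose best-matching cluster maximizes Jaccard overlap
    with the rule-based SC set — reported for visual parity with a heatmap
    reading of the row dendrogram."""
    n = len(proteins)
    if max_clusters is None:
        max_clusters = n
    sc = set(sc_set)
    best = {"n_clusters": 1, "jaccard": 0.0, "members": set(proteins)}
    for k in range(2, min(max_clusters, n) + 1):
        labels = hierarchy.fcluster(result.row_linkage, k, criterion="maxclust")
        for lab in np.unique(labels):
            members = {proteins[i] for i in np.flatnonzero(labels == lab)}
            inter = len(members & sc)
            union = len(members | sc)
            jac = inter / union if union else 0.0
            if jac > best["jaccard"]:
                best = {"n_clusters": int(k), "jaccard": jac, "members": members}
    return best
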