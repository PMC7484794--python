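"""I/O, configuration and the end-to-end corona analysis pipeline.

Reads emPAI tables (CSV/TSV: accession, mw_da, one column per sample),
sample-measurement configs (YAML/JSON, concentrations in ug/ml tags),
FASTA sequence files, and sensorgram CSVs; chains quantification ->
SC identification/classification -> sequence parameters -> coverage
(-> SPR fitting when sensorgrams are provided) and writes CSV/JSON outputs
plus a run manifest with input digests, thresholds and the seed, so every
run is reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .errors import ConfigurationError, ParseError
from . import clustering, coverage, properties, quantification, spr

logger = logging.getLogger("softcorona")

UG_PER_ML_TO_G_PER_ML = 1e-6


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a plain stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_empai_table(path) -> list:
    """Parse an emPAI table into :class:`ProteinRecord` objects.

    Expected header: ``accession, mw_da`` then one column per sample label;
    comma- or tab-separated, UTF-8, decimal point. Blank emPAI cells become
    0 (a count is logged); duplicate accessions are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "accession" or cols[1] != "mw_da":
        raise ParseError(
            f"{path}: header must start 'accession, mw_da, <samples...>', "
            f"got {cols[:3]}"
        )
    dupes = df["accession"][df["accession"].duplicated()].tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate accession(s) {sorted(set(dupes))}")
    sample_cols = cols[2:]
    n_blank = int(df[sample_cols].isna().sum().sum())
    if n_blank:
        logger.warning("%s: %d blank emPAI cell(s) treated as 0", path, n_blank)
    df[sample_cols] = df[sample_cols].fillna(0.0)
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            empai = {c: float(row[2 + i]) for i, c in enumerate(sample_cols)}
            records.append(
                quantification.ProteinRecord(
                    accession=str(row[0]), mw=float(row[1]), empai=empai
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {row_no}: {exc}") from exc
    return records


def read_sample_config(path, captured_label: Optional[str] = None) -> list:
    """Sample measurements from YAML/JSON keyed by sample label.

    Each entry carries ``protein_mass_conc_ug_per_ml`` and
    ``np_number_conc_per_ml``; the captured (HC+SC) sample is marked either
    by a per-entry ``role: captured`` or by ``captured_label``.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping of sample labels")
    samples = []
    for label, entry in data.items():
        try:
            role = entry.get("role", "control")
            if captured_label is not None and label == captured_label:
                role = "captured"
            samples.append(
                quantification.SampleMeasurement(
                    label=str(label),
                    protein_mass_conc=float(entry["protein_mass_conc_ug_per_ml"])
                    * UG_PER_ML_TO_G_PER_ML,
                    np_number_conc=float(entry["np_number_conc_per_ml"]),
                    role=role,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: sample {label!r}: {exc}") from exc
    return samples


def read_fasta(path) -> dict:
    """Accession -> sequence strings from a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_sensorgram(path) -> spr.Sensorgram:
    """Sensorgram from CSV with columns time_s, response_ru, cycle."""
    df = pd.read_csv(path)
    required = {"time_s", "response_ru", "cycle"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    return spr.Sensorgram(
        time=df["time_s"].to_numpy(),
        response=df["response_ru"].to_numpy(),
        cycle=df["cycle"].to_numpy(),
    )


def write_sensorgram(s: spr.Sensorgram, path) -> None:
    pd.DataFrame(
        {"time_s": s.time, "response_ru": s.response, "cycle": s.cycle}
    ).to_csv(path, index=False)


def read_schedule(path) -> spr.InjectionSchedule:
    """Injection schedule from YAML/JSON."""
    data = yaml.safe_load(Path(path).read_text())
    return spr.InjectionSchedule(
        concentrations_nM=tuple(data["concentrations_nM"]),
        t_inject_start=float(data.get("t_inject_start", 0.0)),
        t_inject_end=float(data.get("t_inject_end", 800.0)),
        t_dissoc_end=float(data.get("t_dissoc_end", 2400.0)),
        assoc_window=tuple(data.get("assoc_window", (2.0, 798.0))),
        dissoc_window=tuple(data.get("dissoc_window", (1400.0, 2400.0))),
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_matrix(matrix: quantification.CoronaMatrix, outdir) -> dict:
    """CoronaMatrix as copies/masses CSVs plus a JSON sidecar with M_total."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    copies_path = outdir / "copies_per_np.csv"
    masses_path = outdir / "masses_per_np.csv"
    matrix.copies_frame().rename_axis("accession").to_csv(copies_path)
    matrix.masses_frame().rename_axis("accession").to_csv(masses_path)
    sidecar = {
        "samples": matrix.samples,
        "roles": matrix.roles,
        "m_total_g_per_np": dict(zip(matrix.samples, matrix.m_total.tolist())),
        "avogadro": matrix.avogadro,
        "mw_da": dict(zip(matrix.proteins, matrix.mw.tolist())),
    }
    sidecar_path = outdir / "matrix_meta.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"copies": copies_path, "masses": masses_path, "meta": sidecar_path}


def read_matrix(outdir) -> quantification.CoronaMatrix:
    """Round-trip reader for :func:`write_matrix` outputs."""
    outdir = Path(outdir)
    meta = json.loads((outdir / "matrix_meta.json").read_text())
    copies = pd.read_csv(outdir / "copies_per_np.csv", index_col="accession")
    masses = pd.read_csv(outdir / "masses_per_np.csv", index_col="accession")
    proteins = copies.index.tolist()
    return quantification.CoronaMatrix(
        proteins=proteins,
        samples=meta["samples"],
        roles=meta["roles"],
        copies=copies[meta["samples"]].to_numpy(),
        masses=masses[meta["samples"]].to_numpy(),
        mw=np.array([meta["mw_da"][p] for p in proteins]),
        m_total=np.array([meta["m_total_g_per_np"][s] for s in meta["samples"]]),
        avogadro=meta["avogadro"],
    )


def write_linkage_json(result: clustering.ClusteringResult, path) -> None:
    """Row/column merge trees (merge list + heights) as JSON."""
    def tree(linkage: np.ndarray) -> list:
        return [
            {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in linkage
        ]

    Path(path).write_text(
        json.dumps(
            {
                "rows": tree(result.row_linkage),
                "columns": tree(result.column_linkage),
                "row_order": result.row_order.tolist(),
                "column_order": result.column_order.tolist(),
            },
            indent=2,
        )
    )


def write_grid(grid: spr.KineticGrid, outdir) -> dict:
    """Kinetic grid weights CSV (kd_M, koff_per_s, weight_ru) + diagnostics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kd, koff = grid.nodes()
    weights_path = outdir / "grid_weights.csv"
    pd.DataFrame(
        {"kd_M": kd, "koff_per_s": koff, "weight_ru": grid.weights.ravel()}
    ).to_csv(weights_path, index=False)
    diag = {
        "alpha": grid.alpha,
        "rss": grid.rss,
        "rss_min": grid.rss_min,
        "rss_threshold": grid.rss_threshold,
        "n_points": grid.n_points,
        "parsimony_ok": grid.parsimony_ok,
        "mode": grid.mode,
        "total_signal_ru": grid.total_signal,
    }
    diag_path = outdir / "grid_diagnostics.json"
    diag_path.write_text(json.dumps(diag, indent=2, sort_keys=True))
    return {"weights": weights_path, "diagnostics": diag_path}


def plot_heatmap(matrix, result: clustering.ClusteringResult, path) -> None:
    """Optional clustered z-score heatmap PNG (rows/columns in leaf order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = result.zmatrix[np.ix_(result.row_order, result.column_order)]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(z, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(z.shape[1]))
    ax.set_xticklabels(
        [matrix.samples[i] for i in result.column_order], rotation=45, ha="right"
    )
    ax.set_ylabel("proteins (dendrogram order)")
    fig.colorbar(im, ax=ax, label="z score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths, thresholds and settings of one end-to-end run."""

    empai_table: Path
    sample_config: Path
    output_dir: Path
    fasta: Optional[Path] = None
    sensorgram: Optional[Path] = None
    schedule: Optional[Path] = None
    captured_label: str = quantification.CAPTURED_LABEL
    enrichment_factor: float = clustering.DEFAULT_ENRICHMENT_FACTOR
    max_control_cv: float = clustering.DEFAULT_MAX_CONTROL_CV
    similarity_ratio: float = clustering.DEFAULT_SIMILARITY_RATIO
    np_diameter_nm: float = 70.0
    spr_mode: str = "independent_cycles"
    reg_confidence: float = 0.95
    seed: int = 0
    heatmap: bool = False


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every applicable stage and write the report bundle.

    Returns a manifest dict (also written to ``manifest.json``) with input
    digests, package version, thresholds and output paths. Stage failures
    propagate as package exceptions prefixed with the stage name.
    """
    configure_logging()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "enrichment_factor": cfg.enrichment_factor,
            "max_control_cv": cfg.max_control_cv,
            "similarity_ratio": cfg.similarity_ratio,
            "reg_confidence": cfg.reg_confidence,
        },
        "inputs": {},
        "outputs": {},
    }
    for name in ("empai_table", "sample_config", "fasta", "sensorgram", "schedule"):
        p = getattr(cfg, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _digest(p)}
    logger.info(
        "thresholds: enrichment_factor=%s max_control_cv=%s similarity_ratio=%s",
        cfg.enrichment_factor, cfg.max_control_cv, cfg.similarity_ratio,
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    # quantification
    records = stage("quantify", read_empai_table, cfg.empai_table)
    samples = stage(
        "quantify", read_sample_config, cfg.sample_config, cfg.captured_label
    )
    matrix = stage(
        "quantify", quantification.build_corona_matrix, records, samples
    )
    manifest["outputs"].update(
        {k: str(v) for k, v in write_matrix(matrix, outdir).items()}
    )

    # clustering / classification
    z, _ = stage("classify", clustering.transform_and_scale, matrix)
    clust = stage("classify", clustering.hierarchical_two_way, z)
    sc_set = stage(
        "classify",
        clustering.identify_sc_cluster,
        matrix,
        cfg.enrichment_factor,
        cfg.max_control_cv,
    )
    table = stage(
        "classify", clustering.classify_sc_types, matrix, sc_set,
        cfg.similarity_ratio,
    )
    table_path = outdir / "classification.csv"
    table.to_csv(table_path)
    write_linkage_json(clust, outdir / "linkage.json")
    cut = clustering.best_dendrogram_cut(clust, matrix.proteins, sc_set)
    (outdir / "dendrogram_cut.json").write_text(
        json.dumps(
            {
                "n_clusters": cut["n_clusters"],
                "jaccard": cut["jaccard"],
                "members": sorted(cut["members"]),
            },
            indent=2,
        )
    )
    summary = clustering.composition_summary(matrix, table)
    summary["totals"].to_csv(outdir / "composition_totals.csv")
    summary["percentages"].rename_axis("accession").to_csv(
        outdir / "composition_percentages.csv"
    )
    manifest["outputs"]["classification"] = str(table_path)
    if cfg.heatmap:
        plot_heatmap(matrix, clust, outdir / "heatmap.png")

    # sequence parameters
    if cfg.fasta is not None:
        seqs = stage("params", read_fasta, cfg.fasta)
        params = stage(
            "params", properties.parameters_table, seqs, True
        )
        params.rename_axis("accession").to_csv(outdir / "parameters.csv")
        common = [p for p in matrix.proteins if p in params.index]
        if common:
            j = matrix.captured_index
            weighted = properties.number_weighted_average(
                params.loc[common],
                [matrix.copies[matrix.proteins.index(p), j] for p in common],
            )
            (outdir / "weighted_parameters.json").write_text(
                weighted.to_json(indent=2)
            )
        manifest["outputs"]["parameters"] = str(outdir / "parameters.csv")

    # coverage
    np_spec = coverage.NanoparticleSpec(diameter=cfg.np_diameter_nm)
    footprints = coverage.sphere_footprints(matrix)
    cov = {
        s: coverage.coverage_ratio(matrix, footprints, np_spec, s)
        for s in matrix.samples
    }
    cov_path = outdir / "coverage.csv"
    pd.DataFrame(cov, index=["lower", "upper"]).T.rename_axis("sample").to_csv(
        cov_path
    )
    manifest["outputs"]["coverage"] = str(cov_path)

    # SPR
    if cfg.sensorgram is not None:
        sgram = stage("spr-fit", read_sensorgram, cfg.sensorgram)
        sched = (
            stage("spr-fit", read_schedule, cfg.schedule)
            if cfg.schedule is not None
            else spr.InjectionSchedule()
        )
        grid = stage(
            "spr-fit",
            spr.fit_distribution,
            sgram,
            sched,
            mode=cfg.spr_mode,
            reg_confidence=cfg.reg_confidence,
        )
        manifest["outputs"].update(
            {f"spr_{k}": str(v) for k, v in write_grid(grid, outdir).items()}
        )

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
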