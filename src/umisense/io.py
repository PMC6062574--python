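"""Readers/writers for matrix bundles, molecule tables and run configs."""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .matrix import ENDOGENOUS, SPIKEIN, CountMatrix
from .simdata import MOLECULE_COLUMNS, MoleculeTable

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_matrix_bundle",
    "write_matrix_bundle",
    "read_molecule_table",
    "write_molecule_table",
    "read_spikein_design",
    "RunConfig",
    "run_pipeline",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# matrix bundles (10x-style: matrix.mtx + features.tsv + barcodes.tsv)
# ---------------------------------------------------------------------------
def write_matrix_bundle(cm: CountMatrix, directory: str | Path, prefix: str = "") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx = directory / f"{prefix}matrix.mtx"
    sparse = scipy.sparse.coo_matrix(cm.values)
    scipy.io.mmwrite(str(mtx), sparse, field="integer")
    feat = directory / f"{prefix}features.tsv"
    names = cm.feature_names or cm.feature_ids
    pd.DataFrame(
        {"id": cm.feature_ids, "name": names, "type": cm.feature_types}
    ).to_csv(feat, sep="\t", header=False, index=False)
    bc = directory / f"{prefix}barcodes.tsv"
    pd.Series(cm.barcodes).to_csv(bc, sep="\t", header=False, index=False)
    return [mtx, feat, bc]


def read_matrix_bundle(directory: str | Path, prefix: str = "") -> CountMatrix:
    """Read a matrix.mtx + features.tsv + barcodes.tsv bundle.

    Validates 1-based MatrixMarket indices, sidecar lengths against the
    declared dimensions and id uniqueness; failures raise :class:`FormatError`
    naming the offending file.
    """
    directory = Path(directory)
    mtx = directory / f"{prefix}matrix.mtx"
    feat = directory / f"{prefix}features.tsv"
    bc = directory / f"{prefix}barcodes.tsv"
    for path in (mtx, feat, bc):
        if not path.exists():
            raise FormatError(f"missing bundle file: {path}")
    _validate_mtx_indices(mtx)
    try:
        values = np.asarray(scipy.io.mmread(str(mtx)).todense())
    except Exception as exc:
        raise FormatError(f"{mtx}: {exc}") from exc
    features = pd.read_csv(feat, sep="\t", header=None)
    barcodes = pd.read_csv(bc, sep="\t", header=None)[0].astype(str).tolist()
    feature_ids = features[0].astype(str).tolist()
    if len(feature_ids) != values.shape[0]:
        raise FormatError(
            f"{feat}: {len(feature_ids)} features but matrix has "
            f"{values.shape[0]} rows"
        )
    if len(barcodes) != values.shape[1]:
        raise FormatError(
            f"{bc}: {len(barcodes)} barcodes but matrix has "
            f"{values.shape[1]} columns"
        )
    if len(set(feature_ids)) != len(feature_ids):
        raise FormatError(f"{feat}: duplicate feature ids")
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{bc}: duplicate barcodes")
    ftypes = None
    if features.shape[1] >= 3:
        ftypes = features[2].astype(str).to_numpy()
        bad = set(ftypes) - {ENDOGENOUS, SPIKEIN}
        if bad:
            raise FormatError(f"{feat}: unknown feature types {sorted(bad)}")
    names = (
        features[1].astype(str).tolist() if features.shape[1] >= 2 else None
    )
    return CountMatrix(
        values.astype(np.int64), feature_ids, barcodes, feature_types=ftypes,
        feature_names=names,
    )


def _validate_mtx_indices(path: Path) -> None:
    """Reject 0-based coordinate indices, naming the offending line."""
    with open(path) as fh:
        lineno = 0
        header_seen = False
        for line in fh:
            lineno += 1
            if line.startswith("%"):
                continue
            if not header_seen:  # dims line
                header_seen = True
                continue
            parts = line.split()
            if len(parts) >= 2 and (parts[0] == "0" or parts[1] == "0"):
                raise FormatError(
                    f"{path}: 0-based index on line {lineno} "
                    "(MatrixMarket is 1-based)"
                )


# ---------------------------------------------------------------------------
# molecule tables
# ---------------------------------------------------------------------------
def write_molecule_table(table: MoleculeTable, path: str | Path) -> Path:
    """Write as (optionally gzip) tab-delimited with header."""
    path = Path(path)
    compression = "gzip" if path.suffix == ".gz" else None
    table.df.to_csv(path, sep="\t", index=False, compression=compression)
    return path


def read_molecule_table(path: str | Path) -> MoleculeTable:
    """Read a molecule table; gzip and plain text both accepted.

    Validates the header, (cell, feature, umi) key uniqueness and
    ``reads >= 1``, reporting the offending line number.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"umi": str, "cell": str,
                                              "feature": str})
    missing = [c for c in MOLECULE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = df.index[df["reads"] < 1]
    if len(bad):
        raise FormatError(f"{path}: reads < 1 on data line {bad[0] + 2}")
    dup = df.duplicated(subset=["cell", "feature", "umi"])
    if dup.any():
        raise FormatError(
            f"{path}: duplicate molecule key on data line "
            f"{int(df.index[dup][0]) + 2}"
        )
    return MoleculeTable(df)


# ---------------------------------------------------------------------------
# spike-in design tables
# ---------------------------------------------------------------------------
def read_spikein_design(
    path: str | Path,
    dilution_factor: float | None = None,
    volume_ul: float | None = None,
):
    from .ercc import SpikeInDesign

    df = pd.read_csv(path, sep="\t")
    if "spikein_id" not in df.columns:
        raise FormatError(f"{path}: missing spikein_id column")
    return SpikeInDesign.from_frame(df, dilution_factor, volume_ul)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------
_DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "umisense_run",
    "log_level": "INFO",
    "simdata": {
        "n_cells": 96,
        "n_genes": 2000,
        "mean_expression": 2.0,
        "dispersion": 0.5,
        "capture_efficiency": 0.1,
        "pcr_cycles": 14,
        "pcr_efficiency_alpha": 20.0,
        "pcr_efficiency_beta": 2.0,
        "reads_per_cell": 20000,
        "doublet_rate": 0.0,
        "crosstalk_rate": 0.0,
    },
    "spikeins": {
        "n_levels": 23,
        "min_molecules": 0.12,
        "max_molecules": 10000.0,
        "species_per_level": 4,
    },
    "qc": {"doublet_multiplier": 1.5, "nn_threshold": None},
    "depth": {"depths": [1000, 5000, 10000, 20000], "nested": True},
    "ercc": {"covariate": "log10"},
    "power": {
        "sample_sizes": [24, 48, 96],
        "iterations": 5,
        "de_fraction": 0.1,
        "lfc_sd": 1.5,
        "alpha": 0.05,
        "min_cells_detected": 10,
    },
}


@dataclass
class RunConfig:
    """Validated nested pipeline configuration."""

    data: dict = field(default_factory=lambda: _deep_copy(_DEFAULT_CONFIG))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        merged = _merge_validate(_DEFAULT_CONFIG, user, trail="")
        return cls(merged)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)

    def __getitem__(self, key):
        return self.data[key]


def _deep_copy(d: dict) -> dict:
    return json.loads(json.dumps(d))


def _merge_validate(defaults: dict, user: dict, trail: str) -> dict:
    out = _deep_copy(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise FormatError(f"unknown config key: {trail}{key}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge_validate(defaults[key], val, f"{trail}{key}.")
        else:
            out[key] = val
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute simulate -> qc -> depth -> spike-in sensitivity -> power.

    Writes all artifacts plus the resolved config and a manifest with
    checksums into the run directory, which is returned.  Any stage failure
    halts with the stage name; the partial manifest is persisted.
    """
    from . import __version__, depth as depth_mod, ercc as ercc_mod
    from . import power as power_mod, qc as qc_mod
    from .simdata import SimConfig, simulate_experiment

    cfg = config.data
    outdir = Path(outdir if outdir is not None else cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"version": __version__, "seed": seed, "artifacts": [],
                      "stages": []}

    def _register(path: Path) -> None:
        manifest["artifacts"].append(
            {"path": str(path.relative_to(outdir)), "sha256": _sha256(path)}
        )

    def _write_table(df: pd.DataFrame, name: str, stage: str) -> Path:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# stage={stage} seed={seed} umisense={__version__}\n")
            df.to_csv(fh, sep="\t", index=False)
        _register(path)
        return path

    (outdir / "config.yaml").write_text(config.to_yaml())
    _register(outdir / "config.yaml")

    stage = "simulate"
    try:
        sc = cfg["simdata"]
        sim_config = SimConfig(
            n_cells=sc["n_cells"],
            gene_means=np.full(sc["n_genes"], sc["mean_expression"]),
            gene_dispersions=np.full(sc["n_genes"], sc["dispersion"]),
            capture_efficiency=sc["capture_efficiency"],
            pcr_cycles=sc["pcr_cycles"],
            pcr_efficiency_alpha=sc["pcr_efficiency_alpha"],
            pcr_efficiency_beta=sc["pcr_efficiency_beta"],
            reads_per_cell=sc["reads_per_cell"],
            doublet_rate=sc["doublet_rate"],
            crosstalk_rate=sc["crosstalk_rate"],
            seed=seed,
        )
        design = ercc_mod.geometric_ladder(**cfg["spikeins"])
        bundle = simulate_experiment(sim_config, design)
        for path in write_matrix_bundle(bundle.umi_matrix, outdir / "umi"):
            _register(path)
        for path in write_matrix_bundle(bundle.read_matrix, outdir / "reads"):
            _register(path)
        _register(write_molecule_table(bundle.table, outdir / "molecules.tsv.gz"))
        manifest["stages"].append(stage)

        stage = "qc"
        umi_totals = bundle.umi_matrix.endogenous().values.sum(axis=0)
        dflags, drule = qc_mod.flag_doublets_by_umi(
            umi_totals, cfg["qc"]["doublet_multiplier"]
        )
        nn = qc_mod.nn_correlation(bundle.umi_matrix.endogenous())
        lflags, lrule = qc_mod.flag_low_quality(nn, cfg["qc"]["nn_threshold"])
        qc_df = pd.DataFrame(
            {
                "cell_barcode": bundle.umi_matrix.barcodes,
                "total_umis": umi_totals,
                "nn_correlation": nn,
                "doublet_peak": dflags,
                "low_correlation": lflags,
            }
        )
        _write_table(qc_df, "qc_cells.tsv", stage)
        manifest["rules"] = {"doublet": drule, "low_quality": lrule}
        manifest["stages"].append(stage)

        stage = "depth"
        sat = depth_mod.saturation_curve(
            bundle.table, cfg["depth"]["depths"], seed=seed,
            nested=cfg["depth"]["nested"],
        )
        _write_table(sat, "saturation.tsv", stage)
        manifest["stages"].append(stage)

        stage = "ercc"
        fits = ercc_mod.fit_all_cells(
            bundle.umi_matrix, design, covariate=cfg["ercc"]["covariate"]
        )
        fits_df = pd.DataFrame(
            [
                (f.cell_barcode, f.intercept, f.slope, f.m50, f.converged,
                 f.n_detected, f.n_total)
                for f in fits
            ],
            columns=["cell_barcode", "intercept", "slope", "m50", "converged",
                     "n_detected", "n_total"],
        )
        _write_table(fits_df, "detection_fits.tsv", stage)
        _write_table(ercc_mod.protocol_sensitivity(fits), "sensitivity.tsv", stage)
        manifest["stages"].append(stage)

        stage = "power"
        pw = cfg["power"]
        params = power_mod.estimate_nb_params(
            bundle.umi_matrix.endogenous().values,
            gene_ids=bundle.umi_matrix.endogenous().feature_ids,
            min_cells_detected=pw["min_cells_detected"],
        )
        results, summary = power_mod.power_analysis(
            params,
            sample_sizes=pw["sample_sizes"],
            iterations=pw["iterations"],
            seed=seed,
            de_fraction=pw["de_fraction"],
            lfc_sd=pw["lfc_sd"],
            alpha=pw["alpha"],
        )
        _write_table(results, "power_results.tsv", stage)
        _write_table(summary, "power_summary.tsv", stage)
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
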