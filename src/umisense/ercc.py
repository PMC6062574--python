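"""Spike-in based sensitivity and mRNA-content estimation.

For each cell, detection (>= 1 UMI) of each spike-in species is modelled by a
binomial logistic regression on the known input molecule number, and the
molecule count at 50% detection probability (m50) is derived from the fitted
coefficients.  Cellular mRNA content is estimated by dividing the endogenous
UMI total by the spike-in detection efficiency.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .matrix import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeInDesign",
    "DetectionCurveFit",
    "molecules_from_dilution",
    "detection_table",
    "fit_detection_model",
    "detection_limit",
    "closed_form_limit",
    "protocol_sensitivity",
    "detection_efficiency",
    "estimate_mrna_content",
    "fit_all_cells",
    "geometric_ladder",
    "two_fold_ladder",
]

#: molecules per attomole (Avogadro constant x 1e-18)
MOLECULES_PER_ATTOMOLE = 6.02214076e5


@dataclass
class SpikeInDesign:
    """Known input molecules per cell for each spike-in species."""

    ids: list[str]
    molecules_per_cell: np.ndarray

    def __post_init__(self) -> None:
        self.molecules_per_cell = np.asarray(self.molecules_per_cell, dtype=float)
        if len(self.ids) != self.molecules_per_cell.size:
            raise ValueError("ids and molecules_per_cell must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate spike-in ids")
        if np.any(self.molecules_per_cell < 0):
            raise ValueError("molecules per cell must be >= 0")

    @property
    def total_molecules(self) -> float:
        return float(self.molecules_per_cell.sum())

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        dilution_factor: float | None = None,
        volume_ul: float | None = None,
    ) -> "SpikeInDesign":
        """Build from a table with ``molecules_per_cell`` or ``attomoles_per_ul``."""
        if "molecules_per_cell" in df.columns:
            return cls(list(df["spikein_id"]), df["molecules_per_cell"].to_numpy())
        if "attomoles_per_ul" in df.columns:
            if dilution_factor is None or volume_ul is None:
                raise ValueError(
                    "attomole design needs dilution_factor and volume_ul"
                )
            mols = molecules_from_dilution(
                df["attomoles_per_ul"].to_numpy(), dilution_factor, volume_ul
            )
            return cls(list(df["spikein_id"]), mols)
        raise ValueError(
            "design table needs a molecules_per_cell or attomoles_per_ul column"
        )


def geometric_ladder(
    n_levels: int = 23,
    min_molecules: float = 0.12,
    max_molecules: float = 1e4,
    species_per_level: int = 4,
    prefix: str = "ERCC-",
) -> SpikeInDesign:
    """Spike-in ladder of geometrically spaced abundance levels.

    Defaults give 92 species over 23 levels spanning ~0.12 to 10,000
    molecules per cell, mimicking a diluted external spike-in mix.
    """
    levels = np.geomspace(min_molecules, max_molecules, n_levels)
    mols = np.repeat(levels, species_per_level)
    ids = [f"{prefix}{i:05d}" for i in range(mols.size)]
    return SpikeInDesign(ids, mols)


def two_fold_ladder(
    n_levels: int = 17,
    min_molecules: float = 0.12,
    species_per_level: int = 4,
    prefix: str = "ERCC-",
) -> SpikeInDesign:
    """Strict two-fold dilution ladder: ``min_molecules * 2**k``, k < n_levels.

    Defaults span ~0.12 to ~7,900 molecules per cell.
    """
    levels = min_molecules * 2.0 ** np.arange(n_levels)
    mols = np.repeat(levels, species_per_level)
    ids = [f"{prefix}{i:05d}" for i in range(mols.size)]
    return SpikeInDesign(ids, mols)


@dataclass
class DetectionCurveFit:
    """Per-cell logistic detection fit: logit P(detected) = b0 + b1 * x.

    ``x`` is log10(molecules) by default (``covariate="log10"``).
    """

    cell_barcode: str
    intercept: float
    slope: float
    m50: float
    converged: bool
    n_detected: int
    n_total: int
    covariate: str = "log10"
    reason: str = field(default="", repr=False)


def molecules_from_dilution(
    attomoles_per_ul, dilution_factor: float, volume_ul: float
):
    """Molecules delivered: attomoles/ul x volume / dilution x N_A * 1e-18."""
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    if volume_ul <= 0:
        raise ValueError("volume_ul must be positive")
    return (
        np.asarray(attomoles_per_ul, dtype=float)
        * volume_ul
        / dilution_factor
        * MOLECULES_PER_ATTOMOLE
    )


def detection_table(
    umi_counts: CountMatrix, design: SpikeInDesign, cell: str | int
) -> pd.DataFrame:
    """Per-spike-in detection status (>= 1 UMI) for one cell."""
    j = umi_counts.cell_index(cell) if isinstance(cell, str) else int(cell)
    spikes = umi_counts.spikein()
    lookup = {f: i for i, f in enumerate(spikes.feature_ids)}
    rows = []
    for sid, mols in zip(design.ids, design.molecules_per_cell):
        if sid in lookup:
            count = int(spikes.values[lookup[sid], j])
        else:
            count = 0
            logger.warning("spike-in %s absent from matrix; treated as undetected", sid)
        rows.append((sid, mols, count, int(count >= 1)))
    return pd.DataFrame(rows, columns=["spikein_id", "molecules", "umis", "detected"])


def fit_detection_model(
    table: pd.DataFrame,
    cell_barcode: str = "",
    covariate: str = "log10",
) -> DetectionCurveFit:
    """ML binomial logistic regression of detection on input molecules.

    ``covariate`` is ``"log10"`` (default) or ``"raw"``.  Complete separation
    (all detected or none detected) yields ``converged=False`` rather than an
    exception; fewer than two distinct molecule levels is a usage error.
    """
    mols = np.asarray(table["molecules"], dtype=float)
    det = np.asarray(table["detected"], dtype=float)
    if np.unique(mols).size < 2:
        raise ValueError("need >= 2 distinct molecule levels to fit")
    n_det, n_tot = int(det.sum()), det.size

    def _fail(reason: str) -> DetectionCurveFit:
        return DetectionCurveFit(
            cell_barcode, math.nan, math.nan, math.nan, False, n_det, n_tot,
            covariate, reason,
        )

    if n_det == 0 or n_det == n_tot:
        return _fail("all outcomes identical (separation)")
    if covariate == "log10":
        x = np.log10(mols)
    elif covariate == "raw":
        x = mols
    else:
        raise ValueError(f"unknown covariate scale: {covariate!r}")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            # quasi-separation (a crisp detection transition) still yields a
            # usable crossing point; only all-same outcomes are rejected above
            warnings.simplefilter(
                "ignore", category=sm.tools.sm_exceptions.PerfectSeparationWarning
            )
            res = sm.GLM(det, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8
            )
    except Exception as exc:  # numerical failure, never a crash
        return _fail(f"fit failed: {type(exc).__name__}")
    if not res.converged or not np.all(np.isfinite(res.params)):
        return _fail("IRLS did not converge")
    b0, b1 = float(res.params[0]), float(res.params[1])
    m50 = _m50_from_coeffs(b0, b1, covariate)
    return DetectionCurveFit(cell_barcode, b0, b1, m50, True, n_det, n_tot, covariate)


def _m50_from_coeffs(b0: float, b1: float, covariate: str) -> float:
    if not b1 > 0:
        return math.nan
    x50 = -b0 / b1
    return 10.0 ** x50 if covariate == "log10" else x50


def detection_limit(fit: DetectionCurveFit) -> float:
    """Molecules needed for 50% detection probability (NaN if undefined)."""
    if not fit.converged:
        return math.nan
    return _m50_from_coeffs(fit.intercept, fit.slope, fit.covariate)


def closed_form_limit(p: float) -> float:
    """Analytic m50 for pure binomial capture: ln(0.5) / ln(1 - p)."""
    if not 0 < p < 1:
        raise ValueError("capture probability must be in (0, 1)")
    return math.log(0.5) / math.log(1.0 - p)


def fit_all_cells(
    umi_counts: CountMatrix,
    design: SpikeInDesign,
    covariate: str = "log10",
) -> list[DetectionCurveFit]:
    """Fit the detection model for every cell in the matrix."""
    fits = []
    for barcode in umi_counts.barcodes:
        tab = detection_table(umi_counts, design, barcode)
        fits.append(fit_detection_model(tab, barcode, covariate))
    return fits


def protocol_sensitivity(
    fits: dict[str, list[DetectionCurveFit]] | list[DetectionCurveFit],
) -> pd.DataFrame:
    """Per-group median m50 over converged cells.

    Accepts either a single list of fits (one implicit group) or a mapping
    group -> fits.  Groups with no converged fit report NaN, never silently
    dropped.
    """
    if isinstance(fits, list):
        fits = {"all": fits}
    rows = []
    for group, group_fits in fits.items():
        m50s = [f.m50 for f in group_fits if f.converged and np.isfinite(f.m50)]
        n_excluded = len(group_fits) - len(m50s)
        if n_excluded:
            logger.info(
                "group %s: excluded %d non-converged/undefined fits", group, n_excluded
            )
        median = float(np.median(m50s)) if m50s else math.nan
        rows.append((group, median, len(m50s), n_excluded))
    return pd.DataFrame(
        rows, columns=["group", "median_m50", "n_cells", "n_excluded"]
    )


def detection_efficiency(
    umi_counts: CountMatrix, design: SpikeInDesign, cell: str | int
) -> float:
    """Observed spike-in UMIs over total designed molecules (ratio of sums)."""
    j = umi_counts.cell_index(cell) if isinstance(cell, str) else int(cell)
    spikes = umi_counts.spikein()
    lookup = {f: i for i, f in enumerate(spikes.feature_ids)}
    observed = sum(
        int(spikes.values[lookup[sid], j]) for sid in design.ids if sid in lookup
    )
    total = design.total_molecules
    if total <= 0:
        raise ValueError("design total molecules must be positive")
    eff = observed / total
    if eff > 1:
        logger.warning("cell %s: detection efficiency %.3f > 1", cell, eff)
    return eff


def estimate_mrna_content(
    umi_counts: CountMatrix, design: SpikeInDesign, cell: str | int
) -> float:
    """Endogenous UMI total divided by spike-in detection efficiency.

    NaN when the efficiency is zero (excluded from medians by callers).
    """
    j = umi_counts.cell_index(cell) if isinstance(cell, str) else int(cell)
    eff = detection_efficiency(umi_counts, design, cell)
    if eff == 0:
        logger.warning("cell %s: zero detection efficiency; content undefined", cell)
        return math.nan
    endo_total = int(umi_counts.endogenous().values[:, j].sum())
    return endo_total / eff
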