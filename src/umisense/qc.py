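"""Cell-level quality control and species-mixing crosstalk quantification."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesCall",
    "nn_correlation",
    "flag_low_quality",
    "flag_doublets_by_umi",
    "filter_cells_threshold",
    "assign_species",
    "compare_crosstalk_groups",
]


@dataclass
class SpeciesCall:
    cell_barcode: str
    reads_species_a: int
    reads_species_b: int
    call: str  # "A", "B" or "ambiguous"
    wrong_species_fraction: float  # NaN when total reads is zero


def nn_correlation(umi_counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Per-cell nearest-neighbor Spearman correlation.

    For each cell: the maximum Spearman rank correlation of its expression
    vector against every other cell (ties mid-ranked, self excluded).  Cells
    with constant expression have undefined rank variance and get NaN.
    """
    values = umi_counts.values if isinstance(umi_counts, CountMatrix) else umi_counts
    n_cells = values.shape[1]
    if n_cells < 2:
        raise ValueError("nn_correlation needs at least 2 cells")
    ranks = stats.rankdata(values, axis=0)  # rank genes within each cell
    sd = ranks.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(corr, -np.inf)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    out = np.full(n_cells, np.nan)
    for j in range(n_cells):
        row = corr[j]
        finite = np.isfinite(row)
        if finite.any():
            out[j] = row[finite].max()
    out[constant] = np.nan
    if constant.any():
        logger.warning("%d constant-expression cells: nn correlation undefined",
                       int(constant.sum()))
    return out


def flag_low_quality(
    nn_values: np.ndarray, threshold: float | None = None
) -> tuple[np.ndarray, dict]:
    """Flag cells with anomalously low nearest-neighbor correlation.

    Default rule: nn < median(nn) - 3 * MAD(nn) over cells with defined
    values; when MAD is 0 only cells strictly below the median are flagged.
    A fixed numeric ``threshold`` flags nn < threshold instead.  Returns
    (flags, rule record).
    """
    nn = np.asarray(nn_values, dtype=float)
    finite = np.isfinite(nn)
    if threshold is not None:
        cutoff = float(threshold)
        rule = {"rule": "fixed", "cutoff": cutoff}
    else:
        med = float(np.median(nn[finite]))
        mad = float(stats.median_abs_deviation(nn[finite]))
        cutoff = med if mad == 0 else med - 3 * mad
        rule = {"rule": "median-3mad", "median": med, "mad": mad, "cutoff": cutoff}
    flags = np.zeros(nn.size, dtype=bool)
    flags[finite] = nn[finite] < cutoff
    return flags, rule


def flag_doublets_by_umi(
    umi_totals: np.ndarray, multiplier: float = 1.5
) -> tuple[np.ndarray, dict]:
    """Flag barcodes whose UMI total exceeds ``multiplier`` x the major mode.

    The mode of the per-cell UMI-total distribution is located by Gaussian
    kernel density (Silverman bandwidth).  Returns (flags, rule record).
    """
    totals = np.asarray(umi_totals, dtype=float)
    if totals.size < 5:
        raise ValueError("need >= 5 cells for reliable mode estimation")
    if np.ptp(totals) == 0:
        mode = float(totals[0])
    else:
        kde = stats.gaussian_kde(totals, bw_method="silverman")
        grid = np.linspace(totals.min(), totals.max(), 512)
        mode = float(grid[np.argmax(kde(grid))])
    flags = totals > multiplier * mode
    return flags, {"rule": "kde-mode", "mode": mode, "multiplier": multiplier}


def filter_cells_threshold(
    records: pd.DataFrame,
    min_reads: int = 50_000,
    min_maprate: float = 0.75,
    max_umis: int = 40_000,
    max_genes: int = 5_000,
) -> tuple[list[str], dict[str, int]]:
    """Fixed-threshold cell filters.

    Retains cells with ``total_reads >= min_reads`` and
    ``mapping_rate > min_maprate``; among those, excludes presumed doublets
    with ``total_umis > max_umis`` AND ``genes_detected > max_genes``
    (conjunction).  Returns (retained barcodes, per-rule exclusion counts).
    """
    required = {"cell_barcode", "total_reads", "mapping_rate"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"QC records missing columns: {sorted(missing)}")
    low_reads = records["total_reads"] < min_reads
    low_map = ~low_reads & (records["mapping_rate"] <= min_maprate)
    keep = ~low_reads & ~low_map
    if {"total_umis", "genes_detected"} <= set(records.columns):
        doublet = (
            keep
            & (records["total_umis"] > max_umis)
            & (records["genes_detected"] > max_genes)
        )
    else:
        doublet = pd.Series(False, index=records.index)
    keep = keep & ~doublet
    counts = {
        "low_reads": int(low_reads.sum()),
        "low_maprate": int(low_map.sum()),
        "doublet_threshold": int(doublet.sum()),
    }
    return list(records.loc[keep, "cell_barcode"]), counts


def assign_species(
    barcode: str, reads_a: int, reads_b: int
) -> SpeciesCall:
    """Call a barcode's species by majority of uniquely assigned reads."""
    if reads_a < 0 or reads_b < 0:
        raise ValueError("read counts must be non-negative")
    total = reads_a + reads_b
    if total == 0:
        return SpeciesCall(barcode, reads_a, reads_b, "ambiguous", math.nan)
    if reads_a == reads_b:
        call = "ambiguous"
    else:
        call = "A" if reads_a > reads_b else "B"
    frac = min(reads_a, reads_b) / total
    return SpeciesCall(barcode, reads_a, reads_b, call, frac)


def compare_crosstalk_groups(
    fractions_group1, fractions_group2
) -> tuple[float, float]:
    """Welch two-sample t-test on wrong-species fractions.

    Returns (t statistic, two-sided p).  Degenerate zero-variance identical
    groups give t = 0, p = 1.
    """
    g1 = np.asarray(fractions_group1, dtype=float)
    g2 = np.asarray(fractions_group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if g1.std() == 0 and g2.std() == 0:
        if g1.mean() == g2.mean():
            return 0.0, 1.0
        return math.inf if g1.mean() > g2.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(g1, g2, equal_var=False)
    return float(t), float(p)
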