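"""Read-depth downsampling of molecule tables and saturation statistics.

Downsampling draws exactly ``min(target, total)`` reads per cell without
replacement from the cell's read multiset (multivariate hypergeometric over
molecules).  In nested mode a single per-cell read permutation is shared
across depths, so deeper samples are supersets of shallower ones and
saturation curves are monotone per seed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import cell_rng
from .simdata import MoleculeTable

logger = logging.getLogger(__name__)

__all__ = ["downsample_reads", "saturation_curve", "amplification_evenness"]


def _cell_groups(table: MoleculeTable):
    return table.df.groupby("cell", sort=True)


def _nested_survivors(
    reads: np.ndarray, depths: Sequence[int], rng: np.random.Generator
) -> list[np.ndarray]:
    """Surviving read counts per molecule at each depth, nested by a single
    permutation of the cell's reads."""
    owner = np.repeat(np.arange(reads.size), reads)
    rng.shuffle(owner)
    out = []
    for d in depths:
        d = min(int(d), owner.size)
        out.append(np.bincount(owner[:d], minlength=reads.size))
    return out


def downsample_reads(
    table: MoleculeTable,
    target_depth: int,
    seed: int = 0,
    nested: bool = True,
) -> MoleculeTable:
    """Downsample every cell to exactly ``min(target_depth, total reads)``.

    Molecules left with zero reads are removed.  Cells with fewer reads than
    the target are kept at full depth (and logged), not dropped.  With
    ``nested=True``, smaller depths under the same seed yield subsets of
    larger ones.
    """
    if target_depth < 1:
        raise ValueError("target_depth must be >= 1")
    parts = []
    short = []
    for barcode, grp in _cell_groups(table):
        reads = grp["reads"].to_numpy()
        total = int(reads.sum())
        if total <= target_depth:
            if total < target_depth:
                short.append(barcode)
            parts.append(grp)
            continue
        if nested:
            rng = cell_rng(seed, "downsample", barcode)
            surv = _nested_survivors(reads, [target_depth], rng)[0]
        else:
            rng = cell_rng(seed, "downsample", barcode, int(target_depth))
            surv = rng.multivariate_hypergeometric(reads, target_depth)
        keep = surv > 0
        sub = grp.loc[keep].copy()
        sub["reads"] = surv[keep]
        parts.append(sub)
    if short:
        logger.warning(
            "%d cells have fewer than %d reads; kept at full depth", len(short),
            target_depth,
        )
    df = (
        pd.concat(parts, ignore_index=True)
        if parts
        else table.df.iloc[0:0].copy()
    )
    return MoleculeTable(df)


def saturation_curve(
    table: MoleculeTable,
    depths: Sequence[int],
    seed: int = 0,
    nested: bool = True,
) -> pd.DataFrame:
    """Per-cell detected UMIs / genes at each downsampling depth.

    Returns a tidy frame with columns cell, depth, umis_detected,
    genes_detected, umis_per_read, at_full_depth.  With nested sampling the
    detected counts are non-decreasing in depth for every cell.
    """
    depths = sorted(int(d) for d in depths)
    if not depths or depths[0] < 1:
        raise ValueError("depths must be positive integers")
    rows = []
    for barcode, grp in _cell_groups(table):
        reads = grp["reads"].to_numpy()
        features = grp["feature"].to_numpy()
        total = int(reads.sum())
        if nested:
            rng = cell_rng(seed, "downsample", barcode)
            survivors = _nested_survivors(reads, depths, rng)
        else:
            survivors = []
            for d in depths:
                d_eff = min(d, total)
                rng = cell_rng(seed, "downsample", barcode, int(d))
                survivors.append(rng.multivariate_hypergeometric(reads, d_eff))
        for d, surv in zip(depths, survivors):
            d_eff = min(d, total)
            keep = surv > 0
            umis = int(keep.sum())
            genes = len(set(features[keep]))
            rows.append(
                (barcode, d, umis, genes, umis / d_eff if d_eff else np.nan,
                 d >= total)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell", "depth", "umis_detected", "genes_detected", "umis_per_read",
            "at_full_depth",
        ],
    )


def amplification_evenness(table: MoleculeTable) -> pd.DataFrame:
    """Per-cell reads-per-UMI statistics from the molecule table.

    CV is the population coefficient of variation of reads per molecule;
    undefined (NaN) for cells with fewer than 2 molecules.
    """
    rows = []
    for barcode, grp in _cell_groups(table):
        reads = grp["reads"].to_numpy(dtype=float)
        n = reads.size
        total = reads.sum()
        mean = total / n
        cv = float(reads.std() / mean) if n >= 2 else np.nan
        rows.append((barcode, n, int(total), mean, cv, n / total))
    return pd.DataFrame(
        rows,
        columns=[
            "cell", "n_umis", "total_reads", "mean_reads_per_umi",
            "cv_reads_per_umi", "umis_per_read",
        ],
    )
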