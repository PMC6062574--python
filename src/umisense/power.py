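"""Negative-binomial power simulation for two-group differential expression.

Gene-wise NB parameters (mean and dispersion, ``var = mu + phi * mu**2``) are
estimated from a count matrix by the method of moments on size-factor
normalized counts.  Two-group datasets with a configurable fraction of
differentially expressed genes (log2 fold-changes ~ N(0, sd^2), symmetric
split across groups) are simulated over a grid of per-group sample sizes, a
rank-sum test with Benjamini-Hochberg adjustment calls DE genes, and
TPR/FDR are summarised per sample size.

The published analysis this mirrors used scran normalization and the ROTS
test; here median-of-ratios size factors and the Wilcoxon rank-sum test are
deliberate, documented stand-ins (the test is pluggable via ``test_fn``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seeds import spawn_rngs

logger = logging.getLogger(__name__)

__all__ = [
    "NBGeneParams",
    "size_factors",
    "estimate_nb_params",
    "plant_fold_changes",
    "simulate_two_groups",
    "de_test",
    "bh_adjust",
    "tpr_fdr",
    "power_analysis",
    "smallest_size_reaching",
]

DEFAULT_SAMPLE_SIZES = (24, 48, 96, 192, 384)


@dataclass
class NBGeneParams:
    """Per-gene NB parameters on the normalized scale."""

    gene_ids: list[str]
    means: np.ndarray
    dispersions: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        if not (len(self.gene_ids) == self.means.size == self.dispersions.size):
            raise ValueError("gene_ids, means and dispersions must align")
        if np.any(self.means <= 0):
            raise ValueError("means must be positive")
        if np.any(self.dispersions < 0):
            raise ValueError("dispersions must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.means.size


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, scaled to mean 1.

    Per cell: median of count / geometric mean over genes expressed in every
    cell.  Falls back to library-size factors (with a warning) when no gene
    is expressed in all cells.
    """
    counts = np.asarray(counts, dtype=float)
    all_expressed = (counts > 0).all(axis=1)
    if not all_expressed.any():
        logger.warning(
            "no gene expressed in all cells; using library-size factors"
        )
        libsize = counts.sum(axis=0)
        empty = libsize == 0
        if empty.any():
            logger.warning(
                "%d cells with zero total counts given neutral size factors",
                int(empty.sum()),
            )
            libsize[empty] = libsize[~empty].mean() if (~empty).any() else 1.0
        factors = libsize
    else:
        sub = counts[all_expressed]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        factors = np.median(sub / np.exp(log_geo), axis=0)
    return factors / factors.mean()


def estimate_nb_params(
    counts: np.ndarray,
    gene_ids: list[str] | None = None,
    min_cells_detected: int = 10,
    factors: np.ndarray | None = None,
) -> NBGeneParams:
    """Method-of-moments NB parameter estimates on normalized counts.

    Genes detected (count >= 1) in at least ``min_cells_detected`` cells are
    retained; ``phi = max(0, (var - mean) / mean**2)``.
    """
    counts = np.asarray(counts, dtype=float)
    if gene_ids is None:
        gene_ids = [f"gene_{g:05d}" for g in range(counts.shape[0])]
    if factors is None:
        factors = size_factors(counts)
    detected = (counts > 0).sum(axis=1) >= min_cells_detected
    norm = counts[detected] / factors[None, :]
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.maximum(0.0, (var - mean) / mean**2)
    keep = mean > 0
    ids = [g for g, d in zip(gene_ids, detected) if d]
    return NBGeneParams(
        [g for g, k in zip(ids, keep) if k], mean[keep], phi[keep]
    )


def plant_fold_changes(
    params: NBGeneParams,
    de_fraction: float = 0.10,
    lfc_sd: float = 1.5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Select DE genes and draw their log2 fold-changes.

    ``floor(de_fraction * n_genes)`` genes are picked uniformly; their LFC is
    N(0, lfc_sd^2), all others exactly 0.  Returns (lfcs, is_de).
    """
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_genes
    n_de = int(de_fraction * n)
    lfcs = np.zeros(n)
    is_de = np.zeros(n, dtype=bool)
    idx = rng.choice(n, size=n_de, replace=False)
    lfcs[idx] = rng.normal(0.0, lfc_sd, size=n_de)
    is_de[idx] = True
    return lfcs, is_de


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray, n_cells: int
) -> np.ndarray:
    shape = (mu.size, n_cells)
    lam = np.broadcast_to(mu[:, None], shape).copy()
    over = phi > 0
    if over.any():
        k = (1.0 / phi[over])[:, None]
        theta = (phi[over] * mu[over])[:, None]
        lam[over] = rng.gamma(np.broadcast_to(k, (over.sum(), n_cells)),
                              np.broadcast_to(theta, (over.sum(), n_cells)))
    return rng.poisson(lam).astype(np.int64)


def simulate_two_groups(
    params: NBGeneParams,
    lfcs: np.ndarray,
    n_per_group: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate NB counts for two groups with a symmetric fold-change split.

    Group means are ``mu * 2**(+lfc/2)`` and ``mu * 2**(-lfc/2)``.  Returns
    (counts genes x 2n, group labels of 0/1).
    """
    lfcs = np.asarray(lfcs, dtype=float)
    if lfcs.size != params.n_genes:
        raise ValueError("lfcs length must match number of genes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu1 = params.means * 2.0 ** (lfcs / 2.0)
    mu2 = params.means * 2.0 ** (-lfcs / 2.0)
    g1 = _nb_draw(rng, mu1, params.dispersions, n_per_group)
    g2 = _nb_draw(rng, mu2, params.dispersions, n_per_group)
    counts = np.hstack([g1, g2])
    groups = np.repeat([0, 1], n_per_group)
    return counts, groups


def de_test(
    counts: np.ndarray,
    groups: np.ndarray,
    factors: np.ndarray | None = None,
) -> np.ndarray:
    """Per-gene two-sided Wilcoxon rank-sum p-values on normalized counts.

    Normal approximation with mid-ranks and continuity correction; genes with
    all-identical values get p = 1.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("groups must contain exactly two labels")
    if factors is None:
        with np.errstate(all="ignore"):
            factors = size_factors(counts)
    norm = counts / factors[None, :]
    x = norm[:, groups == labels[0]]
    y = norm[:, groups == labels[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            x, y, axis=1, alternative="two-sided", method="asymptotic"
        )
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.ptp(norm, axis=1) == 0  # tie-only genes: sd of U is 0
    p[constant | ~np.isfinite(p)] = 1.0
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tpr_fdr(
    qvalues: np.ndarray, truth: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """True positive rate and false discovery rate at ``q < alpha``."""
    q = np.asarray(qvalues, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    called = q < alpha
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    n_true = int(truth.sum())
    tpr = tp / n_true if n_true else 0.0
    fdr = fp / max(int(called.sum()), 1)
    return tpr, fdr


def power_analysis(
    params: NBGeneParams,
    sample_sizes=DEFAULT_SAMPLE_SIZES,
    iterations: int = 25,
    seed: int = 0,
    de_fraction: float = 0.10,
    lfc_sd: float = 1.5,
    alpha: float = 0.05,
    test_fn=de_test,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full factorial power simulation over sample sizes and iterations.

    Fresh fold-changes are drawn per iteration.  Returns (per-run results,
    per-size summary).  The summary records the smallest sample size whose
    mean TPR reaches 0.8 in the ``reaches_tpr80`` column.
    """
    rows = []
    rngs = spawn_rngs(seed, "power", iterations)
    for it, rng in enumerate(rngs):
        lfcs, is_de = plant_fold_changes(params, de_fraction, lfc_sd, rng)
        for n in sample_sizes:
            counts, groups = simulate_two_groups(params, lfcs, n, rng)
            pvals = test_fn(counts, groups)
            qvals = bh_adjust(pvals)
            tpr, fdr = tpr_fdr(qvals, is_de, alpha)
            called = int((qvals < alpha).sum())
            rows.append((n, it, tpr, fdr, int(is_de.sum()), called))
    results = pd.DataFrame(
        rows, columns=["n_per_group", "iteration", "tpr", "fdr", "n_de_true",
                       "n_called"],
    )
    summary = (
        results.groupby("n_per_group")
        .agg(
            mean_tpr=("tpr", "mean"),
            q25_tpr=("tpr", lambda s: s.quantile(0.25)),
            q75_tpr=("tpr", lambda s: s.quantile(0.75)),
            mean_fdr=("fdr", "mean"),
        )
        .reset_index()
    )
    summary["reaches_tpr80"] = summary["mean_tpr"] >= 0.8
    return results, summary


def smallest_size_reaching(summary: pd.DataFrame, tpr: float = 0.8) -> int | None:
    """Smallest sample size whose mean TPR reaches ``tpr`` (None if never)."""
    ok = summary.loc[summary["mean_tpr"] >= tpr, "n_per_group"]
    return int(ok.min()) if len(ok) else None
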