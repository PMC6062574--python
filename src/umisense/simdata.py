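"""Molecule-level synthetic scRNA-seq data generator.

The generative chain is:

1. endogenous expression: gamma-Poisson (negative binomial) molecules per
   gene and cell, ``var = mu + phi * mu**2``;
2. spike-in loading: Poisson around the design value (or deterministic
   "fixed" loading), then per-molecule binomial capture;
3. capture: binomial thinning of molecules with probability ``p``;
4. amplification + sequencing: each captured molecule gets an efficiency
   ``e ~ Beta(alpha, beta)`` and weight ``(1 + e)**cycles``; a fixed number of
   reads per cell is allocated over molecules by multinomial sampling;
5. doublet injection: random barcode pairs merged;
6. crosstalk injection: molecules reassigned to random other barcodes.

Every stage records ground truth so downstream estimators can be validated
by parameter recovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._seeds import cell_rng, stage_rng
from .matrix import ENDOGENOUS, SPIKEIN, CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "MoleculeTable",
    "SimBundle",
    "simulate_expression",
    "capture_molecules",
    "spike_in_counts",
    "amplify_and_sequence",
    "inject_doublets",
    "inject_crosstalk",
    "simulate_experiment",
]

MOLECULE_COLUMNS = ["cell", "feature", "umi", "reads"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass(eq=False)
class SimConfig:
    """Parameters of the generative model.

    ``gene_dispersions`` uses the ``var = mu + phi * mu**2`` convention;
    the equivalent NB "size" parameter is ``1 / phi``.
    """

    n_cells: int
    gene_means: np.ndarray
    gene_dispersions: np.ndarray
    capture_efficiency: float = 0.1
    pcr_cycles: int = 14
    pcr_efficiency_alpha: float = 20.0
    pcr_efficiency_beta: float = 2.0
    reads_per_cell: int = 50_000
    doublet_rate: float = 0.0
    crosstalk_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_means = np.asarray(self.gene_means, dtype=float)
        self.gene_dispersions = np.asarray(self.gene_dispersions, dtype=float)
        if self.gene_means.shape != self.gene_dispersions.shape:
            raise ValueError(
                "gene_means and gene_dispersions must have equal length "
                f"({self.gene_means.size} vs {self.gene_dispersions.size})"
            )
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if np.any(self.gene_means <= 0):
            raise ValueError("gene_means must be positive")
        if np.any(self.gene_dispersions < 0):
            raise ValueError("gene_dispersions must be non-negative")
        if not 0 < self.capture_efficiency <= 1:
            raise ValueError("capture_efficiency must be in (0, 1]")
        if self.pcr_cycles < 0:
            raise ValueError("pcr_cycles must be >= 0")
        if self.pcr_efficiency_alpha <= 0 or self.pcr_efficiency_beta <= 0:
            raise ValueError("Beta efficiency parameters must be positive")
        if self.reads_per_cell < 1:
            raise ValueError("reads_per_cell must be >= 1")
        if not 0 <= self.doublet_rate < 0.5:
            raise ValueError("doublet_rate must be in [0, 0.5)")
        if not 0 <= self.crosstalk_rate <= 0.2:
            raise ValueError("crosstalk_rate must be in [0, 0.2]")

    @property
    def n_genes(self) -> int:
        return self.gene_means.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimConfig):
            return NotImplemented
        for name in self.__dataclass_fields__:
            a, b = getattr(self, name), getattr(other, name)
            if isinstance(a, np.ndarray):
                if not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True

    # lossless YAML round-trip
    def to_yaml(self) -> str:
        d = asdict(self)
        d["gene_means"] = [float(x) for x in self.gene_means]
        d["gene_dispersions"] = [float(x) for x in self.gene_dispersions]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Truth record for parameter-recovery tests."""

    true_molecules: np.ndarray
    captured_molecules: np.ndarray
    doublet_flags: dict[str, bool] = field(default_factory=dict)
    doublet_pairs: list[tuple[str, str]] = field(default_factory=list)
    crosstalk_events: int = 0
    per_molecule_amplification: np.ndarray | None = None


# ---------------------------------------------------------------------------
# molecule table
# ---------------------------------------------------------------------------
class MoleculeTable:
    """Table of (cell, feature, umi, reads) records.

    Invariants: the ``(cell, feature, umi)`` key is unique and ``reads >= 1``.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in MOLECULE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"molecule table missing columns: {missing}")
        self.df = df[MOLECULE_COLUMNS].reset_index(drop=True)
        if validate:
            self.validate()

    def validate(self) -> None:
        if len(self.df) and int(self.df["reads"].min()) < 1:
            raise ValueError("molecule reads must be >= 1")
        dup = self.df.duplicated(subset=["cell", "feature", "umi"])
        if dup.any():
            first = self.df[dup].iloc[0]
            raise ValueError(
                "duplicate molecule key "
                f"({first['cell']}, {first['feature']}, {first['umi']})"
            )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MoleculeTable):
            return NotImplemented
        a = self.df.sort_values(MOLECULE_COLUMNS).reset_index(drop=True)
        b = other.df.sort_values(MOLECULE_COLUMNS).reset_index(drop=True)
        return a.equals(b)

    @property
    def total_reads(self) -> int:
        return int(self.df["reads"].sum())

    def cells(self) -> list[str]:
        return sorted(self.df["cell"].unique())

    def umi_counts(
        self,
        feature_ids: Sequence[str] | None = None,
        barcodes: Sequence[str] | None = None,
        reads: bool = False,
    ) -> CountMatrix:
        """Aggregate to a features x cells matrix of UMI (or read) counts."""
        feature_ids = (
            list(feature_ids)
            if feature_ids is not None
            else sorted(self.df["feature"].unique())
        )
        barcodes = list(barcodes) if barcodes is not None else self.cells()
        fidx = {f: i for i, f in enumerate(feature_ids)}
        cidx = {c: j for j, c in enumerate(barcodes)}
        values = np.zeros((len(feature_ids), len(barcodes)), dtype=np.int64)
        grouped = (
            self.df.groupby(["feature", "cell"], sort=False)["reads"]
            .agg("sum" if reads else "size")
            .reset_index()
        )
        for f, c, v in grouped.itertuples(index=False):
            if f in fidx and c in cidx:
                values[fidx[f], cidx[c]] = v
        return CountMatrix(values, feature_ids, barcodes)


@dataclass
class SimBundle:
    """Output of :func:`simulate_experiment`."""

    config: SimConfig
    table: MoleculeTable
    umi_matrix: CountMatrix
    read_matrix: CountMatrix
    truth: GroundTruth


# ---------------------------------------------------------------------------
# generative stages
# ---------------------------------------------------------------------------
def simulate_expression(
    config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw true molecule counts, genes x cells.

    Entry (g, c) is negative binomial with mean ``mu_g`` and dispersion
    ``phi_g`` (gamma-Poisson mixture); ``phi = 0`` degenerates to Poisson.
    """
    rng = rng if rng is not None else stage_rng(config.seed, "expression")
    mu = config.gene_means[:, None]
    phi = config.gene_dispersions[:, None]
    shape = (config.n_genes, config.n_cells)
    if config.n_cells == 0:
        return np.zeros(shape, dtype=np.int64)
    lam = np.broadcast_to(mu, shape).copy()
    over = np.broadcast_to(phi > 0, shape)
    if over.any():
        # gamma with shape 1/phi and scale phi*mu has mean mu, var phi*mu^2
        k = np.broadcast_to(1.0 / np.where(phi > 0, phi, 1.0), shape)
        theta = np.broadcast_to(phi * mu, shape)
        lam[over] = rng.gamma(k[over], theta[over])
    return rng.poisson(lam).astype(np.int64)


def capture_molecules(
    true_counts: np.ndarray, p: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Binomial thinning: each molecule is observed with probability ``p``.

    Implies ``P(detect m molecules) = 1 - (1 - p)**m``.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"capture probability must be in [0, 1], got {p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true_counts = np.asarray(true_counts)
    return rng.binomial(true_counts, p).astype(np.int64)


def spike_in_counts(
    design,
    p: float,
    n_cells: int,
    seed: int | np.random.Generator = 0,
    loading: str = "poisson",
) -> np.ndarray:
    """Simulate spike-in UMI counts, spike-ins x cells.

    ``loading="poisson"`` models physical pipetting of a dilution: the loaded
    copy number per cell is Poisson around the design value.  With
    ``loading="fixed"`` the integer part is loaded deterministically and the
    fractional part as a Bernoulli trial, so the detection probability follows
    the closed form ``1 - (1 - p)**m`` exactly at integer design values.
    """
    molecules = np.asarray(design.molecules_per_cell, dtype=float)
    if np.any(molecules < 0):
        raise ValueError("design molecule values must be >= 0")
    if not 0 <= p <= 1:
        raise ValueError(f"capture probability must be in [0, 1], got {p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.broadcast_to(molecules[:, None], (molecules.size, n_cells))
    if loading == "poisson":
        loaded = rng.poisson(lam)
    elif loading == "fixed":
        frac, whole = np.modf(lam)
        loaded = whole.astype(np.int64) + rng.binomial(1, frac)
    else:
        raise ValueError(f"unknown loading mode: {loading!r}")
    return rng.binomial(loaded, p).astype(np.int64)


def amplify_and_sequence(
    captured: CountMatrix,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[MoleculeTable, np.ndarray]:
    """PCR-amplify captured molecules and sample reads to a fixed depth.

    Each molecule i gets efficiency ``e_i ~ Beta(alpha, beta)`` and weight
    ``(1 + e_i)**cycles``; ``reads_per_cell`` reads are allocated per cell by
    multinomial sampling proportional to the weights.  Molecules with zero
    reads are absent from the output table.  Returns the table and the
    per-molecule amplification weights (table row order).
    """
    seed = config.seed if seed is None else seed
    cells, features, umis, reads_out, weights_out = [], [], [], [], []
    umi_counter = 0
    for j, barcode in enumerate(captured.barcodes):
        counts = captured.values[:, j]
        n_mol = int(counts.sum())
        if n_mol == 0:
            warnings.warn(
                f"cell {barcode} has zero captured molecules; emitting empty cell",
                stacklevel=2,
            )
            continue
        rng = cell_rng(seed, "amplify", barcode)
        eff = rng.beta(config.pcr_efficiency_alpha, config.pcr_efficiency_beta, n_mol)
        w = (1.0 + eff) ** config.pcr_cycles
        reads = rng.multinomial(config.reads_per_cell, w / w.sum())
        feat_per_mol = np.repeat(np.arange(captured.n_features), counts)
        keep = reads > 0
        for gi, r, wi in zip(feat_per_mol[keep], reads[keep], w[keep]):
            cells.append(barcode)
            features.append(captured.feature_ids[gi])
            umis.append(f"m{umi_counter}")
            reads_out.append(int(r))
            weights_out.append(float(wi))
            umi_counter += 1
        umi_counter += int((~keep).sum())  # keep ids globally unique & stable
    df = pd.DataFrame(
        {"cell": cells, "feature": features, "umi": umis, "reads": reads_out}
    )
    return MoleculeTable(df), np.asarray(weights_out)


def inject_doublets(
    table: MoleculeTable,
    rate: float,
    seed: int = 0,
    barcodes: Sequence[str] | None = None,
) -> tuple[MoleculeTable, dict[str, bool], list[tuple[str, str]]]:
    """Merge ``floor(rate * n_cells)`` random barcode pairs.

    UMIs are unioned; a (feature, umi) collision keeps the larger read count.
    Returns (table, per-barcode doublet flags, merged pairs kept->absorbed).
    """
    if not 0 <= rate < 0.5:
        raise ValueError("doublet rate must be in [0, 0.5)")
    barcodes = list(barcodes) if barcodes is not None else table.cells()
    n_pairs = int(rate * len(barcodes))
    flags = {b: False for b in barcodes}
    if n_pairs == 0:
        return table, flags, []
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(barcodes))
    pairs = []
    df = table.df.copy()
    for k in range(n_pairs):
        keep = barcodes[perm[2 * k]]
        absorb = barcodes[perm[2 * k + 1]]
        pairs.append((keep, absorb))
        flags[keep] = True
        df.loc[df["cell"] == absorb, "cell"] = keep
        del flags[absorb]
    # resolve collisions: same (cell, feature, umi) -> max reads
    df = (
        df.groupby(["cell", "feature", "umi"], sort=False, as_index=False)["reads"]
        .max()
    )
    return MoleculeTable(df), flags, pairs


def inject_crosstalk(
    table: MoleculeTable,
    rate: float,
    seed: int = 0,
    barcodes: Sequence[str] | None = None,
) -> tuple[MoleculeTable, int]:
    """Reassign each molecule to a random other barcode with probability ``rate``.

    Molecule count is conserved exactly.  Returns (table, n reassigned).
    """
    if not 0 <= rate <= 0.2:
        raise ValueError("crosstalk rate must be in [0, 0.2]")
    barcodes = list(barcodes) if barcodes is not None else table.cells()
    if rate == 0 or len(barcodes) < 2 or len(table) == 0:
        return table, 0
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    move = rng.random(len(df)) < rate
    n_moved = int(move.sum())
    if n_moved == 0:
        return MoleculeTable(df), 0
    idx = {b: i for i, b in enumerate(barcodes)}
    src = df.loc[move, "cell"].map(idx).to_numpy()
    # uniform over the other n-1 barcodes
    offset = rng.integers(1, len(barcodes), size=n_moved)
    dest = (src + offset) % len(barcodes)
    df.loc[move, "cell"] = [barcodes[d] for d in dest]
    return MoleculeTable(df), n_moved


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------
def simulate_experiment(config: SimConfig, design=None) -> SimBundle:
    """Run the full generative chain and return consistent outputs."""
    barcodes = [f"cell_{j:04d}" for j in range(config.n_cells)]
    gene_ids = [f"gene_{g:05d}" for g in range(config.n_genes)]

    true_endo = simulate_expression(config)
    cap_rng = stage_rng(config.seed, "capture")
    captured_endo = capture_molecules(true_endo, config.capture_efficiency, cap_rng)

    if design is not None:
        spike_rng = stage_rng(config.seed, "spikein")
        spikes = spike_in_counts(
            design, config.capture_efficiency, config.n_cells, spike_rng
        )
        loaded = np.broadcast_to(
            np.asarray(design.molecules_per_cell, float)[:, None],
            (len(design.ids), config.n_cells),
        )
        feature_ids = gene_ids + list(design.ids)
        feature_types = np.array(
            [ENDOGENOUS] * len(gene_ids) + [SPIKEIN] * len(design.ids)
        )
        true_all = np.vstack([true_endo, np.rint(loaded).astype(np.int64)])
        captured_all = np.vstack([captured_endo, spikes])
    else:
        feature_ids = gene_ids
        feature_types = np.array([ENDOGENOUS] * len(gene_ids))
        true_all = true_endo
        captured_all = captured_endo

    captured_cm = CountMatrix(
        captured_all, feature_ids, barcodes, feature_types=feature_types
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, amp = amplify_and_sequence(captured_cm, config)

    table, flags, pairs = inject_doublets(
        table, config.doublet_rate, seed=config.seed + 101, barcodes=barcodes
    )
    surviving = [b for b in barcodes if b in flags]
    table, n_crosstalk = inject_crosstalk(
        table, config.crosstalk_rate, seed=config.seed + 202, barcodes=surviving
    )

    umi_matrix = table.umi_counts(feature_ids, surviving)
    umi_matrix.feature_types = feature_types
    read_matrix = table.umi_counts(feature_ids, surviving, reads=True)
    read_matrix.feature_types = feature_types

    truth = GroundTruth(
        true_molecules=true_all,
        captured_molecules=captured_all,
        doublet_flags=flags,
        doublet_pairs=pairs,
        crosstalk_events=n_crosstalk,
        per_molecule_amplification=amp,
    )
    return SimBundle(config, table, umi_matrix, read_matrix, truth)
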