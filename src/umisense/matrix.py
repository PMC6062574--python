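"""Count matrices with an endogenous / spike-in feature partition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ENDOGENOUS = "endogenous"
SPIKEIN = "spikein"

__all__ = ["CountMatrix", "ENDOGENOUS", "SPIKEIN"]


@dataclass
class CountMatrix:
    """Features x cells matrix of non-negative integer counts.

    Parameters
    ----------
    values
        ``(n_features, n_cells)`` integer array (UMI or read counts).
    feature_ids
        Unique feature identifiers, one per row.
    barcodes
        Unique cell barcodes, one per column.
    feature_types
        Per-feature label, either ``"endogenous"`` or ``"spikein"``.  When
        omitted, features whose id starts with ``spike_prefix`` are labelled
        spike-in.
    """

    values: np.ndarray
    feature_ids: list[str]
    barcodes: list[str]
    feature_types: np.ndarray | None = None
    spike_prefix: str = "ERCC-"
    feature_names: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (features x cells)")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        nf, nc = self.values.shape
        if len(self.feature_ids) != nf:
            raise ValueError(
                f"feature_ids length {len(self.feature_ids)} != {nf} rows"
            )
        if len(self.barcodes) != nc:
            raise ValueError(f"barcodes length {len(self.barcodes)} != {nc} columns")
        if len(set(self.feature_ids)) != nf:
            raise ValueError("duplicate feature ids")
        if len(set(self.barcodes)) != nc:
            raise ValueError("duplicate barcodes")
        if self.feature_types is None:
            self.feature_types = np.array(
                [
                    SPIKEIN if fid.startswith(self.spike_prefix) else ENDOGENOUS
                    for fid in self.feature_ids
                ]
            )
        else:
            self.feature_types = np.asarray(self.feature_types)
            if self.feature_types.shape != (nf,):
                raise ValueError("feature_types length mismatch")
            bad = set(self.feature_types) - {ENDOGENOUS, SPIKEIN}
            if bad:
                raise ValueError(f"unknown feature types: {bad}")

    # -- shape helpers -----------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_index(self, barcode: str) -> int:
        try:
            return self.barcodes.index(barcode)
        except ValueError:
            raise KeyError(f"unknown barcode: {barcode}") from None

    # -- partition ---------------------------------------------------------
    @property
    def spike_mask(self) -> np.ndarray:
        return self.feature_types == SPIKEIN

    def endogenous(self) -> "CountMatrix":
        return self._subset(~self.spike_mask)

    def spikein(self) -> "CountMatrix":
        return self._subset(self.spike_mask)

    def _subset(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(mask)
        return CountMatrix(
            self.values[idx],
            [self.feature_ids[i] for i in idx],
            list(self.barcodes),
            feature_types=self.feature_types[idx],
            spike_prefix=self.spike_prefix,
            feature_names=[self.feature_names[i] for i in idx]
            if self.feature_names is not None
            else None,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and self.feature_ids == other.feature_ids
            and self.barcodes == other.barcodes
            and np.array_equal(self.feature_types, other.feature_types)
        )
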