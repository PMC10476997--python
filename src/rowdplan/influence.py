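"""Sparse per-spot, per-voxel influence data.

``dose`` holds d_ij, the physical dose per unit spot weight delivered by spot
j to voxel i; ``let_dose`` holds n_ij = L_ij * d_ij, the LET-weighted dose
used for dose-averaged LET accumulation. Voxel index i is the C-order flat
index into the associated grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .errors import ConfigurationError, DomainError

__all__ = ["InfluenceData"]


@dataclass
class InfluenceData:
    dose: sparse.csr_matrix  # (n_voxels, n_spots), Gy per unit weight
    let_dose: sparse.csr_matrix  # (n_voxels, n_spots), keV/um * Gy per unit weight
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.dose = sparse.csr_matrix(self.dose)
        self.let_dose = sparse.csr_matrix(self.let_dose)
        if self.dose.shape != self.let_dose.shape:
            raise ConfigurationError("dose and let_dose influence must share shape")
        if self.dose.shape[0] != int(np.prod(self.grid_shape)):
            raise ConfigurationError("influence rows must match the grid voxel count")
        if self.dose.nnz and self.dose.data.min() < 0:
            raise DomainError("influence dose entries must be >= 0")
        if self.let_dose.nnz and self.let_dose.data.min() < 0:
            raise DomainError("influence let_dose entries must be >= 0")

    @property
    def n_spots(self) -> int:
        return self.dose.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.dose.shape[0]

    def check_weights(self, weights: np.ndarray) -> np.ndarray:
        weights = np.asarray(weights, dtype=float).reshape(-1)
        if weights.size != self.n_spots:
            raise ConfigurationError(
                f"expected {self.n_spots} spot weights, got {weights.size}"
            )
        if np.any(weights < 0):
            raise DomainError("spot weights must be >= 0")
        return weights

    def physical_dose(self, weights: np.ndarray) -> np.ndarray:
        """Flat proton dose grid for the given spot weights."""
        return self.dose @ self.check_weights(weights)

    def let_weighted_dose(self, weights: np.ndarray) -> np.ndarray:
        return self.let_dose @ self.check_weights(weights)
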