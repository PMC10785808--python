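"""Distance-fluctuation (DF) analysis.

For every residue pair *(i, j)* the DF score is the trajectory variance of
their Cα–Cα distance,

    DF_ij = ⟨(d_ij − ⟨d_ij⟩)²⟩   [Å²],

with ⟨⟩ a plain (population) average over all frames of the trajectory or
metatrajectory.  Because d_ij is an internal distance, no fitting or
realignment is performed — the score is exactly invariant under per-frame
rigid motion.  Low DF means a pair moves in a coordinated (allosterically
coupled) way; high DF means uncoordinated motion.

The per-residue flattening averages each matrix column over all N pairs a
residue can form, *including the zero self-pair*, giving one "average
(un)coordination felt" score per residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import InsufficientDataError, SelectionError
from .trajectory import ResidueIndexMap, ScoreVector, TrajectoryEnsemble


@dataclass
class DFMatrix:
    """Symmetric N × N matrix of per-pair coordination scores (Å²)."""

    values: np.ndarray
    residue_map: ResidueIndexMap
    n_frames: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("DF matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("DF matrix must be symmetric")
        if np.any(v < 0) or np.any(np.diag(v) != 0):
            raise ValueError("DF matrix must be non-negative with zero diagonal")
        self.values = v

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        residues = list(self.residue_map.author_numbers)
        pd.DataFrame(self.values, index=residues, columns=residues).to_csv(
            path, sep="\t", index_label="residue"
        )

    def plot_heatmap(self, path: str | Path, vmin=None, vmax=None) -> None:
        """Render the matrix as a blue-scale heatmap (unclipped by default)."""
        import matplotlib.pyplot as plt

        residues = self.residue_map.author_numbers
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(
            self.values,
            origin="lower",
            cmap="Blues",
            vmin=vmin,
            vmax=vmax,
            extent=(residues[0], residues[-1], residues[0], residues[-1]),
        )
        fig.colorbar(im, ax=ax, label="DF score (Å$^2$)")
        ax.set_xlabel("residue")
        ax.set_ylabel("residue")
        fig.savefig(path, dpi=150)
        plt.close(fig)


def df_matrix(
    ensemble: TrajectoryEnsemble, discard_initial_ps: float = 0.0
) -> DFMatrix:
    """Pairwise Cα distance-fluctuation matrix of an ensemble.

    The ensemble is restricted to Cα atoms (exactly one per residue
    required).  Accumulation is streaming (Welford running mean / M2 per
    pair), so arbitrarily long concatenated metatrajectories never need a
    distance table in memory.
    """
    ca = ensemble.select(lambda a: a.is_calpha)
    if discard_initial_ps > 0:
        ca = ca.discard_initial(discard_initial_ps)
    residues = ca.residue_numbers
    if len(np.unique(residues)) != len(residues):
        raise SelectionError("ensemble must contain exactly one Calpha per residue")
    if ca.n_frames < 2:
        raise InsufficientDataError("DF needs at least 2 frames")
    n = ca.n_atoms
    n_pairs = n * (n - 1) // 2
    mean = np.zeros(n_pairs)
    m2 = np.zeros(n_pairs)
    for f in range(ca.n_frames):
        d = pdist(ca.coordinates[f])
        delta = d - mean
        mean += delta / (f + 1)
        m2 += delta * (d - mean)
    var = m2 / ca.n_frames  # population variance: plain trajectory average
    return DFMatrix(
        values=squareform(np.maximum(var, 0.0)),
        residue_map=ca.residue_map(),
        n_frames=ca.n_frames,
    )


def df_per_residue(matrix: DFMatrix) -> ScoreVector:
    """Flatten the DF matrix to one score per residue.

    Column sums divided by N — the zero self-pair contributes nothing but
    counts in the divisor, matching the "all N pairs formable by each
    residue, including with itself" convention.
    """
    n = matrix.n_residues
    values = matrix.values.sum(axis=0) / n
    return ScoreVector(
        method_tag="DF",
        residues=np.array(matrix.residue_map.author_numbers),
        values=values,
        polarity="high_means_mobile",
        units="A^2",
    )
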