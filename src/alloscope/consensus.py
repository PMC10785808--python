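"""Cross-method normalization and the consensus heatmap.

Each analysis yields one raw per-residue score S_raw (SPM prominence, 1-D
DF score, snapshot mean Cα deviation, mean backbone RMSD).  To compare them
on one canvas, each vector is min–max rescaled *after* restriction to a
common residue range (by default residues 2–168, because the tail is absent
from the thermal-diffusion analysis):

    S_norm,i = (S_raw,i − min) / (max − min),  min/max over the range only.

The assembled table has one row per method in the fixed order SPM, DF,
DNEMD, ATD.  Values are never polarity-flipped: the SPM row reads the
opposite way round (1 = allosterically central/rigid), and that fact is
carried as metadata and into exports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DegenerateRangeError
from .trajectory import ScoreVector

#: Default common residue range (author numbers, inclusive).
DEFAULT_RESIDUE_RANGE = (2, 168)

METHOD_ORDER = ("SPM", "DF", "DNEMD", "ATD")


def normalize_scores(
    raw: ScoreVector, residue_range: tuple[int, int] = DEFAULT_RESIDUE_RANGE
) -> ScoreVector:
    """Min–max normalize a raw score vector over a residue range.

    The vector is first restricted to the range, then rescaled so its
    minimum maps to 0 and its maximum to 1 (restrict-then-normalize; the
    reverse order gives different values and is deliberately not offered).
    Polarity metadata passes through untouched.  A constant vector has no
    defined rescaling and raises :class:`DegenerateRangeError`.
    """
    restricted = raw.restrict(residue_range)
    if restricted.values.size == 0:
        raise CoverageError(
            f"{raw.method_tag} covers no residues in {residue_range}"
        )
    lo = restricted.values.min()
    hi = restricted.values.max()
    if hi == lo:
        raise DegenerateRangeError(
            f"{raw.method_tag} scores are constant over {residue_range}; "
            "min-max normalization undefined"
        )
    return replace(
        restricted, values=(restricted.values - lo) / (hi - lo), units=""
    )


@dataclass
class ConsensusTable:
    """Methods × residues matrix of normalized scores with polarity metadata."""

    values: pd.DataFrame  # rows: method tags, columns: author residues
    polarity: dict[str, str]
    provenance: dict[str, str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "polarity", [self.polarity[m] for m in out.index])
        out.to_csv(path, sep="\t", index_label="method")

    def plot(
        self,
        path: str | Path,
        annotation_tsv: str | Path | None = None,
        cmap: str = "inferno",
    ) -> None:
        """Render the heatmap; optionally add a residue-range annotation track.

        ``annotation_tsv`` is a 3-column TSV ``start  stop  label`` of author
        residue ranges (e.g. secondary-structure elements).
        """
        import matplotlib.pyplot as plt

        residues = self.values.columns.to_numpy()
        fig, ax = plt.subplots(figsize=(10, 2.6))
        im = ax.imshow(
            self.values.to_numpy(),
            aspect="auto",
            cmap=cmap,
            vmin=0,
            vmax=1,
            extent=(residues[0] - 0.5, residues[-1] + 0.5, self.shape[0] - 0.5, -0.5),
        )
        ax.set_yticks(range(self.shape[0]))
        ax.set_yticklabels(
            [
                m + ("*" if self.polarity[m] == "high_means_rigid" else "")
                for m in self.values.index
            ]
        )
        ax.set_xlabel("residue")
        fig.colorbar(im, ax=ax, label="$S_{norm}$")
        if annotation_tsv is not None:
            ann = pd.read_csv(annotation_tsv, sep="\t")
            for row in ann.itertuples():
                ax.annotate(
                    str(row.label),
                    ((row.start + row.stop) / 2, -0.9),
                    ha="center",
                    fontsize=7,
                    annotation_clip=False,
                )
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def assemble_heatmap(
    vectors: Sequence[ScoreVector],
    residue_range: tuple[int, int] = DEFAULT_RESIDUE_RANGE,
) -> ConsensusTable:
    """Stack four normalized method vectors into the consensus table.

    ``vectors`` must contain exactly the tags SPM, DF, DNEMD and ATD (any
    order; rows come out in that fixed order), each covering every residue
    of ``residue_range``.  Values are taken as given — normalize first with
    :func:`normalize_scores`.
    """
    by_tag = {v.method_tag: v for v in vectors}
    missing = [m for m in METHOD_ORDER if m not in by_tag]
    if missing or len(vectors) != len(METHOD_ORDER):
        raise CoverageError(
            f"need exactly one vector per method {METHOD_ORDER}, missing {missing}"
        )
    lo, hi = residue_range
    columns = np.arange(lo, hi + 1)
    rows = {}
    polarity = {}
    provenance = {}
    for tag in METHOD_ORDER:
        vec = by_tag[tag].restrict(residue_range)
        present = dict(zip(vec.residues, vec.values))
        for r in columns:
            if r not in present:
                raise CoverageError(f"method {tag} is missing residue {r}")
        rows[tag] = [present[r] for r in columns]
        polarity[tag] = vec.polarity
        provenance[tag] = vec.units or "normalized score"
    table = pd.DataFrame(rows, index=columns).T
    if ((table.to_numpy() < 0) | (table.to_numpy() > 1)).any():
        raise ValueError("consensus values must lie in [0, 1]; normalize first")
    return ConsensusTable(values=table, polarity=polarity, provenance=provenance)
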