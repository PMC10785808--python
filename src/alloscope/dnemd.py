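"""Nonequilibrium response averaging (D-NEMD style analysis).

Two pieces, both purely analytical (no simulation here):

* :func:`reactive_filter` — selects equilibrium frames geometrically poised
  for GTP hydrolysis: a nucleophilic water oxygen near the γ-phosphorus and
  a lysine NZ hydrogen-bond distance from one of the γ-oxygens.  Frames
  passing both criteria would seed perturbed windows.

* :func:`deviation_profile` — given matched lists of equilibrium and
  perturbed windows sampled on a common time grid, computes the per-residue,
  per-time mean Cα deviation (|perturbed − equilibrium| position, Å) with
  its standard error over windows.  No superposition is applied before
  measuring the deviation: the perturbed window shares its parent's frame of
  reference by construction, and equal-time comparison cancels ordinary
  diffusion, which is the point of the approach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import PairingError, SelectionError
from .trajectory import ScoreVector, TrajectoryEnsemble

logger = logging.getLogger(__name__)

#: Conventional heavy-atom hydrogen-bond distance (Å), the default for both
#: geometric criteria.
DEFAULT_CUTOFF = 3.5


@dataclass
class ReactiveCriteria:
    """Geometric prerequisites for a frame to count as loosely reactive.

    Both distance cutoffs are mandatory configuration — they default to the
    conventional 3.5 Å heavy-atom hydrogen-bond distance.  The criterion is
    distance-only (no angle term).  ``extra_predicate`` is an optional
    additional frame filter (e.g. a catalytic-glutamine positioning check),
    disabled by default.
    """

    water_o_to_pgamma_max: float = DEFAULT_CUTOFF
    nz_to_ogamma_max: float = DEFAULT_CUTOFF
    pgamma_name: str = "PG"
    ogamma_names: tuple[str, ...] = ("O1G", "O2G", "O3G")
    water_oxygen_name: str = "O"
    water_residue_names: tuple[str, ...] = ("HOH", "WAT", "SOL", "TIP3")
    lys_nz_name: str = "NZ"
    extra_predicate: Callable[[np.ndarray], bool] | None = None

    def __post_init__(self) -> None:
        if self.water_o_to_pgamma_max <= 0 or self.nz_to_ogamma_max <= 0:
            raise ValueError("reactive cutoffs must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "water_o_to_pgamma_max": self.water_o_to_pgamma_max,
                "nz_to_ogamma_max": self.nz_to_ogamma_max,
                "pgamma_name": self.pgamma_name,
                "ogamma_names": list(self.ogamma_names),
                "water_oxygen_name": self.water_oxygen_name,
                "water_residue_names": list(self.water_residue_names),
                "lys_nz_name": self.lys_nz_name,
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ReactiveCriteria":
        data = yaml.safe_load(text)
        data["ogamma_names"] = tuple(data.get("ogamma_names", ("O1G", "O2G", "O3G")))
        data["water_residue_names"] = tuple(
            data.get("water_residue_names", ("HOH", "WAT", "SOL", "TIP3"))
        )
        return cls(**data)


def reactive_filter(
    frames: TrajectoryEnsemble, criteria: ReactiveCriteria
) -> list[int]:
    """Indices (ascending) of frames satisfying both reactive criteria.

    A frame passes iff the *nearest* water oxygen sits within
    ``water_o_to_pgamma_max`` of the γ-phosphorus AND the lysine NZ sits
    within ``nz_to_ogamma_max`` of the *nearest* γ-oxygen (any-water,
    any-Oγ semantics).
    """
    names = [a.atom_name for a in frames.atoms]
    try:
        pg = names.index(criteria.pgamma_name)
    except ValueError:
        raise SelectionError(f"no atom named {criteria.pgamma_name!r}") from None
    try:
        nz = names.index(criteria.lys_nz_name)
    except ValueError:
        raise SelectionError(f"no atom named {criteria.lys_nz_name!r}") from None
    ogamma = [i for i, n in enumerate(names) if n in criteria.ogamma_names]
    if not ogamma:
        raise SelectionError(f"no atoms named {criteria.ogamma_names}")
    waters = [
        i
        for i, a in enumerate(frames.atoms)
        if a.atom_name == criteria.water_oxygen_name
        and a.residue_name in criteria.water_residue_names
    ]
    if not waters:
        raise SelectionError("no water oxygens present")

    kept = []
    for f in range(frames.n_frames):
        xyz = frames.coordinates[f]
        d_water = np.linalg.norm(xyz[waters] - xyz[pg], axis=1).min()
        d_nz = np.linalg.norm(xyz[ogamma] - xyz[nz], axis=1).min()
        ok = (
            d_water <= criteria.water_o_to_pgamma_max
            and d_nz <= criteria.nz_to_ogamma_max
        )
        if ok and criteria.extra_predicate is not None:
            ok = bool(criteria.extra_predicate(xyz))
        if ok:
            kept.append(f)
    return kept


@dataclass
class DeviationProfile:
    """Residues × times mean Cα deviation (Å) with SEM and window counts.

    ``sem`` entries are NaN (undefined) wherever only one window contributes.
    """

    residues: np.ndarray
    times_ps: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_windows: np.ndarray

    def at_time(self, time_ps: float) -> ScoreVector:
        """Per-residue mean deviation at one snapshot time, as a ScoreVector."""
        idx = np.flatnonzero(np.isclose(self.times_ps, time_ps))
        if len(idx) != 1:
            raise KeyError(f"time {time_ps} ps not on the profile grid")
        return ScoreVector(
            method_tag="DNEMD",
            residues=self.residues,
            values=self.mean[:, idx[0]],
            polarity="high_means_mobile",
            units="A",
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for ri, r in enumerate(self.residues):
            for ti, t in enumerate(self.times_ps):
                rows.append(
                    {
                        "residue": int(r),
                        "time_ps": float(t),
                        "mean_A": self.mean[ri, ti],
                        "sem_A": self.sem[ri, ti],
                        "n_windows": int(self.n_windows[ti]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_time_grid() -> np.ndarray:
    """The conventional response-sampling grid: every 2 ps from 6 to 50 ps."""
    return np.arange(6.0, 50.0 + 1e-9, 2.0)


def deviation_profile(
    equilibrium_windows: Sequence[TrajectoryEnsemble],
    perturbed_windows: Sequence[TrajectoryEnsemble],
    time_grid: np.ndarray | None = None,
) -> DeviationProfile:
    """Average per-residue Cα deviation between paired windows over time.

    For every window pair and grid time, the deviation of residue *r* is the
    Euclidean distance between its perturbed and equilibrium Cα positions at
    that time (frames matched by ``frame_times``; windows without times use
    frame order against the grid).  Means and SEMs (sample SD / √W) are
    taken across windows at each (residue, time).
    """
    if len(equilibrium_windows) != len(perturbed_windows):
        raise PairingError(
            f"{len(equilibrium_windows)} equilibrium vs "
            f"{len(perturbed_windows)} perturbed windows"
        )
    if not equilibrium_windows:
        raise PairingError("no windows supplied")
    eq0 = equilibrium_windows[0].calpha()
    residues = eq0.residue_numbers
    if time_grid is None:
        if eq0.frame_times is None:
            raise PairingError("no time grid given and windows carry no frame times")
        time_grid = np.asarray(eq0.frame_times, dtype=float)
    else:
        time_grid = np.asarray(time_grid, dtype=float)

    w = len(equilibrium_windows)
    dev = np.empty((w, len(residues), len(time_grid)))
    for wi, (eq, pert) in enumerate(zip(equilibrium_windows, perturbed_windows)):
        eq_ca = eq.calpha()
        pert_ca = pert.calpha()
        if not np.array_equal(eq_ca.residue_numbers, residues) or not np.array_equal(
            pert_ca.residue_numbers, residues
        ):
            raise PairingError(f"window {wi} does not cover the common residue set")
        eq_idx = _frame_indices(eq_ca, time_grid, wi)
        pert_idx = _frame_indices(pert_ca, time_grid, wi)
        diff = pert_ca.coordinates[pert_idx] - eq_ca.coordinates[eq_idx]
        dev[wi] = np.linalg.norm(diff, axis=2).T
    mean = dev.mean(axis=0)
    if w > 1:
        sem = dev.std(axis=0, ddof=1) / np.sqrt(w)
    else:
        sem = np.full_like(mean, np.nan)  # SEM undefined for a single window
    return DeviationProfile(
        residues=residues,
        times_ps=time_grid,
        mean=mean,
        sem=sem,
        n_windows=np.full(len(time_grid), w, dtype=int),
    )


def _frame_indices(
    window: TrajectoryEnsemble, time_grid: np.ndarray, window_index: int
) -> np.ndarray:
    if window.frame_times is None:
        if window.n_frames != len(time_grid):
            raise PairingError(
                f"window {window_index} has {window.n_frames} frames but no "
                f"times; cannot match a {len(time_grid)}-point grid"
            )
        return np.arange(len(time_grid))
    idx = []
    for t in time_grid:
        hits = np.flatnonzero(np.isclose(window.frame_times, t, atol=1e-6))
        if len(hits) != 1:
            raise PairingError(
                f"window {window_index} does not sample time {t} ps exactly once"
            )
        idx.append(hits[0])
    return np.asarray(idx)
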