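"""Coordinate-ensemble data model, trajectory I/O and superposition utilities.

The central container is :class:`TrajectoryEnsemble`: an ``F × A × 3`` block of
Cartesian coordinates (Å) plus one :class:`AtomRecord` per atom.  All analyses
in this package consume this container; readers exist for multi-model PDB,
a plain CSV fixture dialect, and (through an optional MDAnalysis adapter)
DCD/XTC binary trajectories.

Residues are addressed everywhere by their *author* number (the number a
structural biologist would cite, e.g. 2–185 for a Ras-family GTPase with a
C-terminal hypervariable tail); :class:`ResidueIndexMap` converts between
author numbers and contiguous 0-based internal indices.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    ConsistencyError,
    DegenerateFitError,
    FormatError,
    FormattingError,
    SelectionError,
)

logger = logging.getLogger(__name__)

#: Standard protein backbone heavy atoms.
BACKBONE_HEAVY_NAMES = frozenset({"N", "CA", "C", "O"})

VALID_METHOD_TAGS = ("DF", "SPM", "DNEMD", "ATD")
VALID_POLARITIES = ("high_means_rigid", "high_means_mobile")


@dataclass(frozen=True)
class AtomRecord:
    """Per-atom metadata carried alongside each coordinate column.

    ``author_residue_number`` uses the depositor's numbering; it is never
    remapped internally.  ``is_calpha`` implies ``is_backbone_heavy``.
    """

    author_residue_number: int
    residue_name: str
    atom_name: str
    element: str = ""
    is_backbone_heavy: bool = False
    is_calpha: bool = False

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")
        if self.is_calpha and not self.is_backbone_heavy:
            raise ValueError("a Calpha atom is by definition a backbone heavy atom")

    @classmethod
    def infer(
        cls,
        author_residue_number: int,
        residue_name: str,
        atom_name: str,
        element: str = "",
    ) -> "AtomRecord":
        """Build a record, inferring backbone/Cα flags from the atom name."""
        name = atom_name.strip()
        return cls(
            author_residue_number=int(author_residue_number),
            residue_name=residue_name.strip(),
            atom_name=name,
            element=element.strip() or (name[:1] if name else ""),
            is_backbone_heavy=name in BACKBONE_HEAVY_NAMES,
            is_calpha=name == "CA",
        )


@dataclass(frozen=True)
class ResidueIndexMap:
    """Bijection between author residue numbers and internal indices 0..N−1."""

    author_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        nums = self.author_numbers
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("author residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.author_numbers)

    def to_internal(self, author_number: int) -> int:
        try:
            return self._lookup[author_number]
        except KeyError as exc:
            raise KeyError(f"residue {author_number} not in map") from exc

    def to_author(self, index: int) -> int:
        return self.author_numbers[index]

    @property
    def _lookup(self) -> dict[int, int]:
        # computed lazily; frozen dataclass, so cache on the instance dict
        cached = self.__dict__.get("_lookup_cache")
        if cached is None:
            cached = {a: i for i, a in enumerate(self.author_numbers)}
            self.__dict__["_lookup_cache"] = cached
        return cached


@dataclass
class ScoreVector:
    """One per-residue score per method, with polarity metadata.

    ``polarity`` records how the score reads: ``high_means_mobile`` (DF,
    D-NEMD, ATD — larger means less coordinated / more perturbed) or
    ``high_means_rigid`` (SPM prominence — larger means more central to the
    communication network).
    """

    method_tag: str
    residues: np.ndarray
    values: np.ndarray
    polarity: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.method_tag not in VALID_METHOD_TAGS:
            raise ValueError(f"method_tag must be one of {VALID_METHOD_TAGS}")
        if self.polarity not in VALID_POLARITIES:
            raise ValueError(f"polarity must be one of {VALID_POLARITIES}")
        self.residues = np.asarray(self.residues, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.residues.shape != self.values.shape or self.residues.ndim != 1:
            raise ValueError("residues and values must be matching 1-D arrays")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score values must be finite")

    def restrict(self, residue_range: tuple[int, int]) -> "ScoreVector":
        """Return the sub-vector for author residues lo..hi inclusive."""
        lo, hi = residue_range
        mask = (self.residues >= lo) & (self.residues <= hi)
        return replace(self, residues=self.residues[mask], values=self.values[mask])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.residues, name=self.method_tag)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"residue": self.residues, "score": self.values})
        df.to_csv(path, sep="\t", index=False)


@dataclass
class TrajectoryEnsemble:
    """Frames × atoms × 3 coordinate block (Å) with shared atom metadata."""

    coordinates: np.ndarray
    atoms: tuple[AtomRecord, ...]
    frame_times: np.ndarray | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (F, A, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        self.atoms = tuple(self.atoms)
        if len(self.atoms) != self.coordinates.shape[1]:
            raise ConsistencyError(
                f"{len(self.atoms)} atom records for "
                f"{self.coordinates.shape[1]} coordinate columns"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.coordinates.shape[0],):
                raise ValueError("frame_times must have one entry per frame")

    # -- basic views ------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, index: int) -> np.ndarray:
        return self.coordinates[index]

    def select(self, predicate: Callable[[AtomRecord], bool]) -> "TrajectoryEnsemble":
        """Sub-ensemble of atoms satisfying ``predicate`` (frame order kept)."""
        mask = np.array([bool(predicate(a)) for a in self.atoms])
        if not mask.any():
            raise SelectionError("selection keeps no atoms")
        return TrajectoryEnsemble(
            coordinates=self.coordinates[:, mask, :],
            atoms=tuple(a for a, keep in zip(self.atoms, mask) if keep),
            frame_times=self.frame_times,
            source_label=self.source_label,
        )

    def calpha(self) -> "TrajectoryEnsemble":
        """Cα-only view, the anchor selection for per-residue analyses."""
        return self.select(lambda a: a.is_calpha)

    def residue_map(self) -> ResidueIndexMap:
        numbers: list[int] = []
        for a in self.atoms:
            if not numbers or a.author_residue_number != numbers[-1]:
                numbers.append(a.author_residue_number)
        return ResidueIndexMap(tuple(numbers))

    @property
    def residue_numbers(self) -> np.ndarray:
        """Author residue number of each atom column."""
        return np.array([a.author_residue_number for a in self.atoms])

    def discard_initial(self, time_ps: float) -> "TrajectoryEnsemble":
        """Drop frames earlier than ``time_ps`` (requires frame times)."""
        if time_ps <= 0:
            return self
        if self.frame_times is None:
            raise ValueError("discard_initial needs frame_times on the ensemble")
        mask = self.frame_times >= time_ps
        if not mask.any():
            raise ValueError("discarding removes every frame")
        return TrajectoryEnsemble(
            coordinates=self.coordinates[mask],
            atoms=self.atoms,
            frame_times=self.frame_times[mask],
            source_label=self.source_label,
        )

    # -- serialization ----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the fixture dialect: frame,residue,atom_name,x,y,z."""
        frames = np.repeat(np.arange(self.n_frames), self.n_atoms)
        res = np.tile(self.residue_numbers, self.n_frames)
        names = [a.atom_name for a in self.atoms] * self.n_frames
        xyz = self.coordinates.reshape(-1, 3)
        pd.DataFrame(
            {
                "frame": frames,
                "residue": res,
                "atom_name": names,
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
            }
        ).to_csv(path, sep=",", index=False)

    def to_pdb(self, path: str | Path) -> None:
        Path(path).write_text(self.to_pdb_text())

    def to_pdb_text(self, b_factors: np.ndarray | None = None) -> str:
        """Multi-model PDB text; optional per-atom B-factor column."""
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        stack = struc.AtomArrayStack(self.n_frames, self.n_atoms)
        stack.coord = self.coordinates.astype(np.float32)
        stack.chain_id = np.full(self.n_atoms, "A")
        stack.res_id = self.residue_numbers
        stack.res_name = np.array([a.residue_name or "UNK" for a in self.atoms])
        stack.atom_name = np.array([a.atom_name for a in self.atoms])
        stack.element = np.array([a.element or a.atom_name[:1] for a in self.atoms])
        stack.hetero = np.zeros(self.n_atoms, dtype=bool)
        if b_factors is not None:
            stack.set_annotation("b_factor", np.asarray(b_factors, dtype=float))
        pdb = PDBFile()
        pdb.set_structure(stack)
        buf = io.StringIO()
        pdb.write(buf)
        return buf.getvalue()


def concatenate(
    ensembles: Sequence[TrajectoryEnsemble], discard_initial_ps: float = 0.0
) -> TrajectoryEnsemble:
    """Concatenate replicas into one metatrajectory.

    ``discard_initial_ps`` drops the head of *each* replica before joining
    (the usual equilibration discard, applied per replica).
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    parts = [e.discard_initial(discard_initial_ps) for e in ensembles]
    atoms = parts[0].atoms
    for p in parts[1:]:
        if p.atoms != atoms:
            raise ConsistencyError("replicas disagree on atom identity")
    times = None
    if all(p.frame_times is not None for p in parts):
        times = np.concatenate([p.frame_times for p in parts])
    return TrajectoryEnsemble(
        coordinates=np.concatenate([p.coordinates for p in parts], axis=0),
        atoms=atoms,
        frame_times=times,
        source_label="+".join(p.source_label for p in parts),
    )


# ---------------------------------------------------------------------------
# Readers


def read_trajectory(
    path: str | Path,
    format: str,
    selection: Callable[[AtomRecord], bool] | None = None,
    topology: str | Path | None = None,
) -> TrajectoryEnsemble:
    """Read a coordinate ensemble.

    Parameters
    ----------
    path
        Trajectory file.
    format
        One of ``pdb_multimodel``, ``csv``, ``dcd``, ``xtc``.  The binary
        formats additionally require ``topology`` (a PDB file) and the
        optional MDAnalysis adapter.
    selection
        Optional predicate on :class:`AtomRecord`; only matching atoms are
        kept (must keep at least one).
    """
    readers = {
        "pdb_multimodel": _read_pdb_multimodel,
        "csv": _read_csv,
        "dcd": _read_mdanalysis,
        "xtc": _read_mdanalysis,
    }
    if format not in readers:
        raise FormatError(f"unknown format {format!r}")
    if format in ("dcd", "xtc"):
        ensemble = _read_mdanalysis(path, topology)
    else:
        ensemble = readers[format](path)
    if selection is not None:
        ensemble = ensemble.select(selection)
    return ensemble


def _read_pdb_multimodel(path: str | Path) -> TrajectoryEnsemble:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite raises assorted parse errors
        raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc
    models = []
    for m in range(1, n_models + 1):
        try:
            models.append(pdb.get_structure(model=m))
        except Exception as exc:
            raise FormatError(f"cannot parse model {m} of {path}: {exc}") from exc
    counts = {len(m) for m in models}
    if len(counts) != 1:
        raise ConsistencyError(
            f"models of {path} have differing atom counts: {sorted(counts)}"
        )
    first = models[0]
    for m in models[1:]:
        if not (
            np.array_equal(m.atom_name, first.atom_name)
            and np.array_equal(m.res_id, first.res_id)
        ):
            raise ConsistencyError(f"models of {path} disagree on atom identity")
    atoms = tuple(
        AtomRecord.infer(rid, rname, aname, elem)
        for rid, rname, aname, elem in zip(
            first.res_id, first.res_name, first.atom_name, first.element
        )
    )
    coords = np.stack([m.coord for m in models]).astype(float)
    return TrajectoryEnsemble(coords, atoms, source_label=str(path))


def _read_csv(path: str | Path) -> TrajectoryEnsemble:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
    required = {"frame", "residue", "atom_name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"CSV fixture needs columns {sorted(required)}, got {list(df.columns)}"
        )
    frames = sorted(df["frame"].unique())
    groups = [df[df["frame"] == f] for f in frames]
    key0 = list(zip(groups[0]["residue"], groups[0]["atom_name"]))
    for f, g in zip(frames, groups):
        if list(zip(g["residue"], g["atom_name"])) != key0:
            raise ConsistencyError(f"frame {f} of {path} disagrees on atom identity")
    atoms = tuple(AtomRecord.infer(r, "UNK", n) for r, n in key0)
    coords = np.stack([g[["x", "y", "z"]].to_numpy(float) for g in groups])
    return TrajectoryEnsemble(coords, atoms, source_label=str(path))


def _read_mdanalysis(path: str | Path, topology: str | Path | None) -> TrajectoryEnsemble:
    if topology is None:
        raise FormatError("binary trajectory formats require a topology file")
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - adapter is optional
        raise FormatError(
            "DCD/XTC support requires the optional MDAnalysis adapter "
            "(pip install alloscope[traj])"
        ) from exc
    u = mda.Universe(str(topology), str(path))
    atoms = tuple(
        AtomRecord.infer(a.resid, a.resname, a.name, getattr(a, "element", ""))
        for a in u.atoms
    )
    coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory]).astype(float)
    times = np.array([ts.time for ts in u.trajectory])
    return TrajectoryEnsemble(coords, atoms, frame_times=times, source_label=str(path))


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Rigid-body superposition of one frame onto another (Kabsch).

    Finds the proper rotation + translation minimizing the RMSD of the
    ``fit_mask`` atoms, applies it to *all* atoms of ``mobile`` and returns
    ``(fitted_frame, fit_rmsd)``.

    Raises
    ------
    DegenerateFitError
        If the fit set has fewer than 3 atoms or is collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (A, 3) arrays")
    if fit_mask is None:
        fit_idx = np.arange(mobile.shape[0])
    else:
        fit_mask = np.asarray(fit_mask)
        fit_idx = np.flatnonzero(fit_mask) if fit_mask.dtype == bool else fit_mask
    if len(fit_idx) < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    mob_fit = mobile[fit_idx]
    ref_fit = reference[fit_idx]
    mob_c = mob_fit.mean(axis=0)
    ref_c = ref_fit.mean(axis=0)
    centered = mob_fit - mob_c
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] <= 1e-8 * max(svals[0], 1.0):
        raise DegenerateFitError("fit atoms are (near-)collinear")
    rot, _ = Rotation.align_vectors(ref_fit - ref_c, centered)
    if np.linalg.det(rot.as_matrix()) < 0:  # pragma: no cover - scipy guarantees
        raise DegenerateFitError("improper rotation returned")
    fitted = rot.apply(mobile - mob_c) + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((fitted[fit_idx] - ref_fit) ** 2, axis=1))))
    return fitted, rmsd


# ---------------------------------------------------------------------------
# Score export


def write_scores_to_pdb(
    coordinates: np.ndarray,
    atoms: Sequence[AtomRecord],
    scores: ScoreVector,
    fill_value: float = 0.0,
    path: str | Path | None = None,
) -> str:
    """Project per-residue scores into the PDB B-factor column.

    Every atom of a scored residue carries that residue's score in columns
    61–66 (``%6.2f``); atoms of unscored residues carry ``fill_value`` and a
    warning is logged.  Values that do not fit the fixed-width field raise
    :class:`FormattingError` (rescale before export).
    """
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim != 3:
        coordinates = coordinates[None, :, :]
    lookup = {int(r): float(v) for r, v in zip(scores.residues, scores.values)}
    per_atom = []
    missing: list[int] = []
    for a in atoms:
        if a.author_residue_number in lookup:
            per_atom.append(lookup[a.author_residue_number])
        else:
            per_atom.append(fill_value)
            if a.author_residue_number not in missing:
                missing.append(a.author_residue_number)
    for v in set(per_atom):
        if len(f"{v:6.2f}") > 6:
            raise FormattingError(
                f"score {v} does not fit the %6.2f B-factor field; "
                "rescale scores before export"
            )
    if missing:
        logger.warning(
            "no score for residues %s; B-factor filled with %.2f", missing, fill_value
        )
    ensemble = TrajectoryEnsemble(coordinates, tuple(atoms))
    text = ensemble.to_pdb_text(b_factors=np.array(per_atom))
    if path is not None:
        Path(path).write_text(text)
    return text
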