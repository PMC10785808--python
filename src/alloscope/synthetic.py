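"""Synthetic coordinate ensembles with planted allosteric structure.

Real equilibrium trajectories of a membrane-anchored GTPase are far beyond
desk scale, so this module generates ensembles that carry the *statistical*
features the four analyses read out:

* a regular helical Cα chain (3.8 Å consecutive spacing) as reference
  geometry, so the 6 Å contact graph has non-trivial short-range edges;
* Gaussian equilibrium fluctuations with block-structured residue
  correlations — a rigid, internally correlated core versus weakly coupled
  surroundings, optionally with an extra-flexible tail mimicking a
  hypervariable region;
* paired equilibrium/perturbed window sets carrying a spatially decaying
  displacement field, the stand-in for a nonequilibrium (post-perturbation)
  response;
* a mock active-site frame (γ-phosphate, its Oγ atoms, a water oxygen and a
  lysine NZ) at exact requested distances, for testing the reactive-frame
  geometric filter.

Everything is driven by explicit integer seeds: same seed, same bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .errors import CovarianceSpecError, GeometryError, PerturbationSpecError
from .trajectory import AtomRecord, TrajectoryEnsemble

#: Canonical consecutive Cα–Cα distance in a polypeptide chain (Å).
CA_SPACING = 3.8


def make_reference_chain(
    n_residues: int,
    rise: float | None = 1.5,
    turn: float = 100.0,
    radius: float | None = None,
    first_residue: int = 2,
) -> np.ndarray:
    """One Cα per residue on a regular helix with 3.8 Å spacing.

    Exactly one of ``rise``/``radius`` may be left ``None``; it is solved so
    that consecutive Cα atoms sit ``CA_SPACING`` apart.  The defaults
    (rise 1.5 Å, turn 100°) give an α-helix-like geometry with radius
    ≈ 2.28 Å, whose i → i+3 contacts fall inside a 6 Å cutoff.

    Returns the ``(n_residues, 3)`` coordinates; pair with
    :func:`chain_atoms` to build an ensemble.
    """
    if n_residues < 2:
        raise GeometryError("a chain needs at least 2 residues")
    theta = math.radians(turn)
    chord = 2.0 * (1.0 - math.cos(theta))
    if rise is None and radius is None:
        raise GeometryError("specify rise or radius (the other is solved)")
    if radius is None:
        assert rise is not None
        h2 = CA_SPACING**2 - rise**2
        if h2 < 0 or (chord <= 0 and h2 > 0):
            raise GeometryError(
                f"rise {rise} Å and turn {turn}° cannot give {CA_SPACING} Å spacing"
            )
        radius = math.sqrt(h2 / chord) if chord > 0 else 0.0
    elif rise is None:
        r2 = CA_SPACING**2 - radius**2 * chord
        if r2 <= 0:
            raise GeometryError(
                f"radius {radius} Å and turn {turn}° cannot give {CA_SPACING} Å spacing"
            )
        rise = math.sqrt(r2)
    spacing = math.sqrt(rise**2 + radius**2 * chord)
    if abs(spacing - CA_SPACING) > 1e-6:
        raise GeometryError(
            f"parameters give {spacing:.6f} Å consecutive spacing, not {CA_SPACING}"
        )
    k = np.arange(n_residues)
    coords = np.column_stack(
        [radius * np.cos(k * theta), radius * np.sin(k * theta), k * rise]
    )
    d = np.linalg.norm(coords[None, :, :] - coords[:, None, :], axis=-1)
    far = ~np.eye(n_residues, dtype=bool) & ~np.eye(n_residues, k=1, dtype=bool) & ~np.eye(
        n_residues, k=-1, dtype=bool
    )
    if n_residues > 2 and d[far].min() <= 2.0:
        raise GeometryError("chain self-intersects (non-neighbour pair closer than 2 Å)")
    return coords


def chain_atoms(n_residues: int, first_residue: int = 2) -> tuple[AtomRecord, ...]:
    """Cα atom records for a synthetic chain, author-numbered from ``first_residue``."""
    return tuple(
        AtomRecord.infer(first_residue + i, "ALA", "CA") for i in range(n_residues)
    )


@dataclass
class CovarianceSpec:
    """Block-structured residue covariance for equilibrium sampling.

    Each block is a half-open internal-index range ``(start, stop)`` with an
    intra-block correlation ``rho_in``; every other residue pair shares the
    background correlation ``rho_out``.  ``sigma`` is the per-residue
    displacement standard deviation (Å), scalar or length-N.
    """

    blocks: tuple[tuple[tuple[int, int], float], ...]
    rho_out: float = 0.0
    sigma: float | Sequence[float] = 0.5

    def __post_init__(self) -> None:
        for (start, stop), rho in self.blocks:
            if not 0 <= rho < 1:
                raise CovarianceSpecError(f"rho_in {rho} outside [0, 1)")
            if stop <= start:
                raise CovarianceSpecError(f"empty block range ({start}, {stop})")
        rho_ins = [rho for _, rho in self.blocks]
        if rho_ins and not 0 <= self.rho_out < min(rho_ins):
            raise CovarianceSpecError("rho_out must lie in [0, min rho_in)")

    def correlation(self, n_residues: int) -> np.ndarray:
        """The N × N residue correlation matrix this spec implies."""
        corr = np.full((n_residues, n_residues), self.rho_out)
        for (start, stop), rho in self.blocks:
            if stop > n_residues:
                raise CovarianceSpecError(
                    f"block ({start}, {stop}) exceeds chain length {n_residues}"
                )
            corr[start:stop, start:stop] = rho
        np.fill_diagonal(corr, 1.0)
        return corr

    def covariance(self, n_residues: int) -> np.ndarray:
        sigma = np.broadcast_to(np.asarray(self.sigma, dtype=float), (n_residues,))
        if np.any(sigma < 0):
            raise CovarianceSpecError("sigma must be non-negative")
        cov = self.correlation(n_residues) * np.outer(sigma, sigma)
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-8:
            raise CovarianceSpecError(
                f"implied covariance not PSD (min eigenvalue {eigvals.min():.3e})"
            )
        return cov

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "blocks": [
                    {"start": s, "stop": e, "rho_in": r} for (s, e), r in self.blocks
                ],
                "rho_out": self.rho_out,
                "sigma": np.asarray(self.sigma, dtype=float).tolist(),
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "CovarianceSpec":
        data = yaml.safe_load(text)
        sigma = data["sigma"]
        return cls(
            blocks=tuple(
                ((b["start"], b["stop"]), b["rho_in"]) for b in data["blocks"]
            ),
            rho_out=data["rho_out"],
            sigma=sigma if np.isscalar(sigma) else np.asarray(sigma, dtype=float),
        )


def sample_equilibrium_ensemble(
    reference: np.ndarray,
    spec: CovarianceSpec,
    n_frames: int,
    seed: int,
    frame_times: np.ndarray | None = None,
    first_residue: int = 2,
    source_label: str = "synthetic-equilibrium",
) -> TrajectoryEnsemble:
    """Sample Gaussian frames around ``reference`` with ``spec`` covariance.

    The residue covariance acts identically and independently on x, y and z
    (a Kronecker product with the 3 × 3 identity).  Deterministic in
    ``seed``.
    """
    reference = np.asarray(reference, dtype=float)
    n = reference.shape[0]
    cov = spec.covariance(n)
    # symmetric PSD square root (eigendecomposition tolerates the rho_in→1 edge)
    eigvals, eigvecs = np.linalg.eigh(cov)
    root = eigvecs @ (np.sqrt(np.clip(eigvals, 0.0, None))[:, None] * eigvecs.T)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, 3, n))
    disp = np.einsum("fka,na->fkn", z, root)  # (F, 3, N) with residue covariance
    coords = reference[None, :, :] + disp.transpose(0, 2, 1)
    return TrajectoryEnsemble(
        coordinates=coords,
        atoms=chain_atoms(n, first_residue),
        frame_times=frame_times,
        source_label=source_label,
    )


@dataclass
class PerturbationSpec:
    """A planted, spatially decaying displacement field.

    Residue *i* is shifted by ``amplitude * exp(-d_i / decay_length)`` along
    ``direction``, where ``d_i`` is its reference-frame distance to the
    nearest site residue (author numbers).  ``direction`` may be a unit
    3-vector or the string ``"random per window"``.  ``noise_sd`` adds
    independent Gaussian noise per coordinate of the perturbed copies.
    """

    site_residues: tuple[int, ...]
    amplitude: float = 2.0
    decay_length: float = 30.0
    noise_sd: float = 0.0
    direction: tuple[float, float, float] | str = "random per window"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise PerturbationSpecError("amplitude must be non-negative")
        if self.decay_length <= 0:
            raise PerturbationSpecError("decay_length must be positive")
        if self.noise_sd < 0:
            raise PerturbationSpecError("noise_sd must be non-negative")
        if not self.site_residues and self.amplitude > 0:
            raise PerturbationSpecError("site_residues empty with amplitude > 0")
        if isinstance(self.direction, str):
            if self.direction != "random per window":
                raise PerturbationSpecError(f"unknown direction {self.direction!r}")
        else:
            d = np.asarray(self.direction, dtype=float)
            if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-9:
                raise PerturbationSpecError("direction must be a unit 3-vector")

    def field_amplitudes(
        self, reference: np.ndarray, residue_numbers: np.ndarray
    ) -> np.ndarray:
        """The planted per-residue displacement magnitudes (Å), analytically."""
        if not self.site_residues:
            return np.zeros(len(reference))
        sites = np.flatnonzero(np.isin(residue_numbers, list(self.site_residues)))
        if len(sites) == 0:
            raise PerturbationSpecError(
                f"site residues {self.site_residues} not present in the chain"
            )
        d = np.linalg.norm(
            reference[:, None, :] - reference[None, sites, :], axis=-1
        ).min(axis=1)
        return self.amplitude * np.exp(-d / self.decay_length)

    def to_yaml(self) -> str:
        direction = (
            self.direction
            if isinstance(self.direction, str)
            else list(map(float, self.direction))
        )
        return yaml.safe_dump(
            {
                "site_residues": list(self.site_residues),
                "amplitude": self.amplitude,
                "decay_length": self.decay_length,
                "noise_sd": self.noise_sd,
                "direction": direction,
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PerturbationSpec":
        data = yaml.safe_load(text)
        direction = data["direction"]
        if not isinstance(direction, str):
            direction = tuple(direction)
        return cls(
            site_residues=tuple(data["site_residues"]),
            amplitude=data["amplitude"],
            decay_length=data["decay_length"],
            noise_sd=data["noise_sd"],
            direction=direction,
        )


def make_perturbed_windows(
    equilibrium_windows: Sequence[TrajectoryEnsemble],
    spec: PerturbationSpec,
    seed: int,
    reference: np.ndarray | None = None,
) -> list[TrajectoryEnsemble]:
    """Perturbed copies of equilibrium windows carrying the planted field.

    Each perturbed window is its equilibrium partner plus the decaying
    displacement field (distances measured once, in ``reference`` — by
    default the first frame of the first window) plus optional Gaussian
    noise.  The equilibrium windows are left untouched.
    """
    if not equilibrium_windows:
        raise PerturbationSpecError("need at least one equilibrium window")
    if reference is None:
        reference = equilibrium_windows[0].frame(0)
    residue_numbers = equilibrium_windows[0].residue_numbers
    amplitudes = spec.field_amplitudes(np.asarray(reference, float), residue_numbers)
    rng = np.random.default_rng(seed)
    perturbed = []
    for window in equilibrium_windows:
        if isinstance(spec.direction, str):
            v = rng.standard_normal(3)
            direction = v / np.linalg.norm(v)
        else:
            direction = np.asarray(spec.direction, dtype=float)
        shift = amplitudes[:, None] * direction[None, :]
        coords = window.coordinates + shift[None, :, :]
        if spec.noise_sd > 0:
            coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
        perturbed.append(
            TrajectoryEnsemble(
                coordinates=coords,
                atoms=window.atoms,
                frame_times=window.frame_times,
                source_label=window.source_label + "+perturbation",
            )
        )
    return perturbed


def make_reactive_fixture(
    water_to_pgamma: float, nz_to_ogamma: float
) -> TrajectoryEnsemble:
    """One-frame mock active site at exact requested distances.

    Contains a γ-phosphorus ``PG`` with its three ``O1G/O2G/O3G`` oxygens, a
    water oxygen at ``water_to_pgamma`` Å from PG, and a lysine ``NZ`` at
    ``nz_to_ogamma`` Å from O1G (and farther from the other two Oγ), matching
    the reactive-frame filter's selection contract exactly.
    """
    if water_to_pgamma <= 0 or nz_to_ogamma <= 0:
        raise PerturbationSpecError("fixture distances must be positive")
    pg = np.zeros(3)
    o1g = np.array([0.0, 0.0, 1.5])
    o2g = np.array([1.3, 0.0, -0.75])
    o3g = np.array([-1.3, 0.0, -0.75])
    water = np.array([water_to_pgamma, 0.0, 0.0])
    nz = o1g + np.array([0.0, 0.0, nz_to_ogamma])
    coords = np.stack([nz, pg, o1g, o2g, o3g, water])[None, :, :]
    atoms = (
        AtomRecord(16, "LYS", "NZ", "N"),
        AtomRecord(200, "GTP", "PG", "P"),
        AtomRecord(200, "GTP", "O1G", "O"),
        AtomRecord(200, "GTP", "O2G", "O"),
        AtomRecord(200, "GTP", "O3G", "O"),
        AtomRecord(300, "HOH", "O", "O"),
    )
    return TrajectoryEnsemble(coords, atoms, source_label="reactive-fixture")
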