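"""Thermal-diffusion response analysis (ATD style).

Each window is a short production run started from a supercooled state in
which only the ligand was reheated; allosteric coupling to the ligand is
read from how far each residue's backbone has moved by the end of the run
relative to its beginning.  Concretely, per window:

1. superpose the endpoint frame(s) onto the window's first frame using the
   backbone heavy atoms {N, CA, C, O} of residues up to ``max_fit_residue``
   (the flexible C-terminal tail is excluded from the fit — including it
   swamps the signal in alignment noise);
2. per residue, take the RMSD of its backbone heavy atoms between the
   fitted endpoint and the first frame;
3. average over windows.

Residues above ``max_fit_residue`` (default 168, i.e. tail residues 169+)
are excluded from both the fit and the reported scores.  ``endpoint``
selects the last frame only (default) or the mean over all frames after the
first — the literature phrasing is compatible with either, so both are
offered and the choice is logged.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, SelectionError
from .trajectory import ScoreVector, TrajectoryEnsemble, kabsch_superpose

logger = logging.getLogger(__name__)

DEFAULT_MAX_FIT_RESIDUE = 168


def atd_response(
    windows: Sequence[TrajectoryEnsemble],
    max_fit_residue: int = DEFAULT_MAX_FIT_RESIDUE,
    fit_residues: Sequence[int] | None = None,
    endpoint: str = "last_frame",
) -> ScoreVector:
    """Mean per-residue backbone RMSD of window endpoints vs. window starts.

    Parameters
    ----------
    windows
        Production-run ensembles (≥2 frames each, backbone heavy atoms
        present; a Cα-only ensemble analyses the Cα alone).
    max_fit_residue
        Residues with author number above this are dropped from fit and
        output alike.
    fit_residues
        Optional explicit author-number set for the fit (still intersected
        with ``max_fit_residue``); by default all analysed residues.
    endpoint
        ``"last_frame"`` or ``"per_frame_mean"``.
    """
    if endpoint not in ("last_frame", "per_frame_mean"):
        raise ValueError("endpoint must be 'last_frame' or 'per_frame_mean'")
    if not windows:
        raise InsufficientDataError("no windows supplied")
    logger.info("ATD endpoint mode: %s; max fit residue %d", endpoint, max_fit_residue)

    first = windows[0].select(
        lambda a: a.is_backbone_heavy and a.author_residue_number <= max_fit_residue
    )
    residues = np.array(sorted(set(first.residue_numbers)))
    per_window = np.empty((len(windows), len(residues)))
    for wi, window in enumerate(windows):
        if window.n_frames < 2:
            raise InsufficientDataError(f"window {wi} has fewer than 2 frames")
        bb = window.select(
            lambda a: a.is_backbone_heavy and a.author_residue_number <= max_fit_residue
        )
        if not np.array_equal(np.unique(bb.residue_numbers), residues):
            raise SelectionError(f"window {wi} does not cover the common residue set")
        atom_res = bb.residue_numbers
        if fit_residues is None:
            fit_mask = np.ones(bb.n_atoms, dtype=bool)
        else:
            fit_mask = np.isin(atom_res, np.asarray(list(fit_residues)))
            if fit_mask.sum() < 3:
                raise SelectionError("fit selection keeps fewer than 3 atoms")
        start = bb.frame(0)
        frame_ids = (
            [bb.n_frames - 1] if endpoint == "last_frame" else range(1, bb.n_frames)
        )
        rmsd_acc = np.zeros(len(residues))
        for fi in frame_ids:
            fitted, _ = kabsch_superpose(bb.frame(fi), start, fit_mask)
            sq = np.sum((fitted - start) ** 2, axis=1)
            for ri, r in enumerate(residues):
                sel = atom_res == r
                rmsd_acc[ri] += np.sqrt(sq[sel].mean())
        per_window[wi] = rmsd_acc / len(list(frame_ids))
    return ScoreVector(
        method_tag="ATD",
        residues=residues,
        values=per_window.mean(axis=0),
        polarity="high_means_mobile",
        units="A",
    )
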