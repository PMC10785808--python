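"""Thermal-diffusion response: endpoint-vs-start backbone RMSD per residue.

Plants a 2 Å displacement of one residue between a window's first and last
frame (fit held on the other residues) and shows exact recovery, then runs
the same analysis on sampled fluctuation windows.
"""

import numpy as np

import alloscope as al

ref = al.make_reference_chain(60)
atoms = al.chain_atoms(60)

last = ref.copy()
last[5] += np.array([2.0, 0.0, 0.0])  # residue 7 (author numbering from 2)
window = al.TrajectoryEnsemble(np.stack([ref, last]), atoms)
score = al.atd_response([window], fit_residues=[r for r in range(2, 62) if r != 7])
idx = score.residues.tolist().index(7)
print(f"planted 2.0 A displacement of residue 7 recovered as "
      f"{score.values[idx]:.6f} A; all other residues < "
      f"{np.delete(score.values, idx).max():.1e} A")

spec = al.CovarianceSpec(blocks=(((20, 40), 0.9),), rho_out=0.05, sigma=0.3)
ens = al.sample_equilibrium_ensemble(ref, spec, 100, seed=3)
windows = [al.TrajectoryEnsemble(ens.coordinates[2 * w : 2 * w + 2], atoms)
           for w in range(50)]
response = al.atd_response(windows)
print(f"mean response over 50 fluctuation windows: {response.values.mean():.3f} A "
      f"(high = residue drifts far from its window start)")
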