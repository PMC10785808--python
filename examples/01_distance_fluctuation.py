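"""Distance-fluctuation analysis of a synthetic ensemble with a rigid core.

Builds a 60-residue helical chain whose central residues 22–41 fluctuate as
a correlated block, computes the pairwise DF matrix and its per-residue
flattening, and prints the most and least coordinated residues.
"""

import numpy as np

import alloscope as al

ref = al.make_reference_chain(60)
spec = al.CovarianceSpec(blocks=(((20, 40), 0.9),), rho_out=0.05, sigma=0.3)
ens = al.sample_equilibrium_ensemble(ref, spec, 400, seed=1)

matrix = al.df_matrix(ens)
scores = al.df_per_residue(matrix)

order = np.argsort(scores.values)
print(f"DF matrix: {matrix.n_residues} x {matrix.n_residues} over {matrix.n_frames} frames")
print("most coordinated residues (lowest DF, allosterically coupled):",
      scores.residues[order[:5]].tolist())
print("least coordinated residues (highest DF):",
      scores.residues[order[-5:]].tolist())
print(f"mean DF inside planted core: "
      f"{scores.values[(scores.residues >= 22) & (scores.residues < 42)].mean():.3f} A^2")
print(f"mean DF elsewhere:           "
      f"{scores.values[(scores.residues < 22) | (scores.residues >= 42)].mean():.3f} A^2")
# Low DF = concerted motion: the planted core should come out clearly lower.
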