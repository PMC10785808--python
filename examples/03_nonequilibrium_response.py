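"""Reactive-frame filtering and nonequilibrium response averaging.

First screens mock active-site frames with the geometric reactive filter,
then recovers a planted, spatially decaying displacement field from 500
paired equilibrium/perturbed windows.
"""

import numpy as np

import alloscope as al

# -- reactive filter on mock active-site geometry --------------------------
criteria = al.ReactiveCriteria()  # both cutoffs 3.5 A
near = al.make_reactive_fixture(water_to_pgamma=3.0, nz_to_ogamma=2.8)
far = al.make_reactive_fixture(water_to_pgamma=5.0, nz_to_ogamma=2.8)
print("reactive filter: near-water frame kept:", al.reactive_filter(near, criteria) == [0])
print("reactive filter: far-water frame kept: ", al.reactive_filter(far, criteria) == [0])

# -- response averaging over 500 window pairs ------------------------------
ref = al.make_reference_chain(60)
spec = al.CovarianceSpec(blocks=(), sigma=0.3)
grid = np.array([10.0])
eq = [al.sample_equilibrium_ensemble(ref, spec, 1, seed=1000 + w, frame_times=grid)
      for w in range(500)]
pspec = al.PerturbationSpec(site_residues=(2,), amplitude=2.0, decay_length=30.0,
                            noise_sd=0.005)
pert = al.make_perturbed_windows(eq, pspec, seed=7, reference=ref)

profile = al.deviation_profile(eq, pert, grid)
planted = pspec.field_amplitudes(ref, np.arange(2, 62))
print(f"site residue 2: mean deviation {profile.mean[0, 0]:.4f} A "
      f"(planted 2.0000 A, SEM {profile.sem[0, 0]:.5f})")
err = np.abs(profile.mean[:, 0] - planted)
print(f"worst residue: |estimate - planted| = {err.max():.5f} A "
      f"= {(err / profile.sem[:, 0]).max():.2f} SEM")
# The averaged deviation reproduces the planted decaying field within a few
# standard errors at every residue.
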