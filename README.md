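# alloscope

Multi-method analysis of allosteric communication in a single protein chain,
for computational structural biologists working with molecular-dynamics
coordinate ensembles. Allostery — the propagation of a perturbation at one
site to behaviour at a distant site — leaves different fingerprints in
different observables, so `alloscope` implements four complementary
"languages" plus their cross-method consensus:

1. **Distance fluctuation (DF).** For residues *i, j* with Cα–Cα distance
   *d<sub>ij</sub>* per frame,
   DF<sub>ij</sub> = ⟨(d<sub>ij</sub> − ⟨d<sub>ij</sub>⟩)²⟩ (Å²), a plain
   trajectory variance needing no fitting or realignment. Low DF = the pair
   moves in a concerted, allosterically coupled way. The matrix flattens to
   one score per residue by averaging each column over all *N* pairs a
   residue can form (self pair included).
2. **Shortest path map (SPM).** Residues become graph nodes; an edge joins
   residues whose mean Cα distance stays below 6 Å and carries length
   *l<sub>ij</sub>* = −ln |C<sub>ij</sub>|, where
   C<sub>ij</sub> = ⟨Δ**r**<sub>i</sub>·Δ**r**<sub>j</sub>⟩ /
   √(⟨|Δ**r**<sub>i</sub>|²⟩⟨|Δ**r**<sub>j</sub>|²⟩) is the displacement
   cross-correlation relative to the medoid of the most populated
   conformational cluster. One shortest path is computed per residue pair
   (deterministic Dijkstra); edge usage is normalized so the busiest edge
   weighs 1, the map keeps edges above 0.3, and each residue's *prominence*
   counts the paths visiting it as an intermediate.
3. **Nonequilibrium response averaging (D-NEMD style).** Given paired
   equilibrium/perturbed windows, the per-residue deviation is the Euclidean
   distance between perturbed and equilibrium Cα positions at equal times —
   no superposition — averaged over windows with its SEM. A geometric
   reactive-frame filter (nucleophilic water near the γ-phosphate, lysine NZ
   hydrogen-bonded to a γ-oxygen) selects frames eligible to seed windows.
4. **Thermal-diffusion response (ATD style).** Per window, the backbone
   {N, CA, C, O} RMSD each residue reaches by the window's end relative to
   its first frame, after fitting on the backbone of residues ≤ 168 (the
   flexible C-terminal tail is excluded), averaged over windows.

The **consensus** module min–max rescales each method's per-residue score
over a common residue range (default 2–168) to S<sub>norm</sub> ∈ [0, 1]
and stacks them into a methods × residues heatmap; the SPM row carries
opposite polarity metadata (1 = rigid/communicating) from the other three
(1 = mobile/perturbed).

Because production trajectories at the scale this kind of study needs are
far beyond desk scale, `alloscope.synthetic` generates ensembles with
*planted* allosteric structure — a correlated rigid core, decaying
displacement fields, mock active-site geometry — so every stage is testable
and demonstrable end-to-end.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```sh
$ python examples/01_distance_fluctuation.py
DF matrix: 60 x 60 over 400 frames
most coordinated residues (lowest DF, allosterically coupled): [24, 31, 38, 36, 27]
least coordinated residues (highest DF): [9, 19, 51, 14, 48]
mean DF inside planted core: 0.117 A^2
mean DF elsewhere:           0.165 A^2
```

The ensemble plants a correlated core at residues 22–41; the lowest
(most coordinated) DF scores land inside it, and the core's mean DF is well
below the rest of the chain. The consensus example ties all four methods
together:

```sh
$ python examples/05_consensus_heatmap.py
consensus table: 4 methods x 60 residues
  SPM    core mean 0.40, overall mean 0.27 (1 = rigid/communicating)
  DF     core mean 0.04, overall mean 0.56 (1 = mobile/perturbed)
  DNEMD  core mean 0.20, overall mean 0.28 (1 = mobile/perturbed)
  ATD    core mean 0.12, overall mean 0.50 (1 = mobile/perturbed)
```

The planted core reads as *rigid and communicating* in every language:
above-average SPM prominence, below-average DF, response deviation and
endpoint RMSD — with the SPM row's chromatic trend deliberately opposite,
as flagged by its polarity metadata.

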