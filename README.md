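# membmode

Analysis toolkit for the binding geometry of peripheral membrane proteins
on lipid bilayers, built around the case of a secreted phospholipase A2
(sPLA2) on a POPC bilayer.  A peripheral enzyme does not sit on the
membrane in a single orientation: it can adopt several distinct **binding
modes**, each characterized by a reproducible set of residues in lipid
contact and a characteristic **altitude** — the height of the protein's
top surface above the membrane's phosphorus plane.  `membmode` provides
the complete analysis chain by which such modes are identified and
quantified, from two independent kinds of raw data:

* **simulation trajectories** — protein–lipid contact maps, landing
  detection, contact-fingerprint clustering of orientations, per-residue
  RMSF, altitude distributions;
* **AFM height images** of proteins on a supported bilayer — globule
  detection, background-plane estimation, and deconvolution of the pooled
  altitude sample into K Gaussian populations.

Both branches meet in the same observable (altitude populations), from
which Boltzmann energetics follow: for mode occupancies `p_i` at
temperature `T`, the energy of mode `j` relative to mode `i` is

```
ΔE_ij = −k_B · T · ln(p_j / p_i)
```

and the allowed switching path between modes is constrained to pairs of
modes whose contact regions overlap or neighbour each other on the
protein surface.  A Kabsch superposition module converts coarse-grained
poses back to atomistic structures by fitting Cα atoms onto backbone
beads.

Because real microsecond trajectories and wet AFM data are not shippable,
the package includes a first-class synthetic-data module that plants
ground truth with the characteristic values of the system it emulates: a
134-residue protein, three modes with altitudes **1.74 / 2.37 / 2.90 nm**,
contact sets of 17 / 10 / 6 residues (adjacent only for consecutive
modes), and mode occupancies **(0.430, 0.346, 0.224)** — the deepest mode
at 43 % with the 2→3 switch costing exactly twice the energy of 1→2.
Every analysis routine is tested by recovering these planted parameters.

## Worked example

Six synthetic trajectories are started from different orientations with
the planted mapping start 1 → mode 1, starts 2/4/5/6 → mode 2,
start 3 → mode 3, then analysed blind:

```python
from membmode.pipeline import RunConfig, run_md_branch

report = run_md_branch(RunConfig(seed=7, md={"simulate": {"n_frames": 200}}))
```

prints (via the report fields):

```
n_modes: 3
labels: {'start1': 1, 'start2': 2, 'start4': 2, 'start5': 2, 'start6': 2, 'start3': 3}
mode 1: members=['start1']                                altitude=1.737 nm  contacts/frame=17.0  stable_residues=17
mode 2: members=['start2', 'start4', 'start5', 'start6']  altitude=2.371 nm  contacts/frame=10.0  stable_residues=10
mode 3: members=['start3']                                altitude=2.901 nm  contacts/frame=6.0   stable_residues=6
overlap: {'1-2': 'overlapping', '1-3': 'disjoint', '2-3': 'overlapping'}
path: [1, 2, 3]
```

The six starts collapse into exactly three modes; mode numbering follows
contact intensity (mode 1 binds deepest and touches the most residues);
the recovered altitudes match the planted centres to ~0.005 nm; and since
the mode-1 and mode-3 contact regions share no residues and sit on
opposite faces of the globule, the 1→3 orientation switch must pass
through mode 2.

The same machinery is exposed as a CLI
(`membmode simulate|contacts|modes|altitude|afm|energy|backmap|run`);
exit codes are 0 (success), 2 (usage), 3 (bad data).

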