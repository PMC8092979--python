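# Methods

## Problem and scope

`allopath` post-processes steered-MD output for allosteric proteins — the
working example is *E. coli* aspartokinase III (AKIII), a
lysine-feedback-inhibited enzyme whose T-state structure (PDB 2J0X) is used
purely as a residue-numbering reference.  The pipeline never runs MD; it
consumes (a) a per-residue energy decomposition over trajectory snapshots
(five force-field components: bond, angle, dihedral, electrostatic, van der
Waals, in kJ/mol), (b) optionally a coordinate trajectory as multi-model
PDB, and (c) optionally a per-residue conservation-score table.  From these
it reproduces the standard analysis chain:

1. **Mobility bookkeeping** — global backbone superposition of every frame
   on the starting configuration, per-residue backbone RMSD over a trailing
   window, and a strict `> 10 Å` high-mobility filter.
2. **Energy-change bookkeeping** — per-component start-vs-end differences
   per residue, with strict `|Δtotal| > 8 kJ/mol` and
   `|Δelectrostatic| > 5 kJ/mol` responsiveness filters.
3. **Energy-term correlation** — a 7×7 Pearson matrix over the five
   components plus the conformational (bond+angle+dihedral) and non-bond
   (electrostatic+vdW) composites, to read off energy
   transformation/compensation structure.
4. **Residue correlation networks** — the R×R Pearson matrix of one energy
   term (electrostatic by default) across residues, thresholded at
   `> +0.5` / `< −0.5`, clustered by connected components.
5. **C-score pathway inference** — for a source residue A in the regulatory
   site and a sink residue B in the catalytic site, every other residue X is
   scored `C(X) = Cor(A,X)·Cor(X,B)`; members are residues with `C > 0.3`.
   With 3 lysine-site sources and 4 aspartate-site sinks this yields a
   12-pathway grid; residues shared by all pathways form the transduction
   backbone, summarised by their mean conservation score.

## Statistical model of the synthetic generator

No per-residue energy decomposition of AKIII is publicly available, so the
package ships a generator that plants exactly the statistical structure the
analysis is designed to detect, with a manifest sufficient to predict every
recovery statistic.

**Latent pathway factor.**  A single standard-normal series `F` (one value
per snapshot, no autocorrelation) drives the electrostatic energy of the
source, sink and backbone residues.  A planted residue with loading
`l ∈ (0,1]` has unit-variance electrostatic signal
`z = l·F + sqrt(1−l²)·ε`, so the expected Pearson correlation between two
planted residues is the product of their loadings (0.81 at the default
`l = 0.9`) and the expected C score of a backbone residue is
`(l²)² ≈ 0.66` — comfortably above the 0.3 membership threshold, while an
unplanted residue's C score is the product of two null correlations
(each `O(1/√N)`), far below it.  The amplitude scale `noise_sigma`
(kJ/mol) multiplies the unit-variance signal and therefore never affects a
correlation.

**Compensation coupling.**  Every residue's dihedral series is
`ρ·z_elec + sqrt(1−ρ²)·ε'` with `ρ = compensation_rho = −0.5`, so the
electrostatic–dihedral correlation is ρ at the single-residue level and at
the pooled-matrix level.  Coupling *every* residue (not only the planted
ones) is deliberate: energy transformation between the electrostatic and
covalent terms is a global property of the trajectory, and it is what makes
the pooled 7×7 matrix estimate of ρ consistent.  Van der Waals amplitude
defaults to 5 % of the electrostatic amplitude, making the non-bond
composite electrostatics-dominated (corr ≈ 1/√(1+0.05²) ≈ 0.9988) — the
regime in which the term-matrix sign pattern (electrostatic–dihedral < 0,
conformational–non-bond < 0, non-bond–electrostatic > 0.99) is expected.

**End-state offsets.**  Optional per-residue, per-term offsets are added on
a schedule that is 0 until 90 % of the trajectory, rises linearly to 1 at
98 %, and holds the plateau to the end.  A trailing window of up to 2 % of
the snapshots therefore averages the full offset, so windowed start-vs-end
differences are unbiased, while the literal final-minus-first-frame reading
(`window = 1`) remains noise-dominated — the reason windowed differences
are the default.

**Coordinate toy.**  The coordinate generator builds a backbone-only
(N, CA, C, O) ideal helix; a short loop (by default ~2 % of the chain,
starting a quarter of the way along) is rigidly translated 12 Å in the
final 10 % of frames; small positional noise (0.02 Å per coordinate) and a
random proper rigid transform per frame are added so that superposition is
actually exercised.  The loop is kept to a few percent of the chain because
a global least-squares fit is dragged by displaced atoms in proportion to
their mass fraction; at the default scale the scaffold stays below 1 Å
while the loop exceeds 10 Å.

**Determinism.**  Every stream is a `numpy` PCG64 generator keyed by
`[seed, residue_id]` (the latent factor uses a key outside the residue-id
range), so identical configs give bit-identical output and adding residues
never perturbs existing streams.

**What the generator does not emulate.**  Physical force-field energetics
(no bonded geometry, no 1/r terms), autocorrelated dynamics (snapshots are
exchangeable), anharmonic or multi-state kinetics, and solvent effects.
Passing recovery tests therefore demonstrates that the *statistical
machinery* — correlation estimation, thresholding, C-score intersection —
behaves as designed at the study's problem size, not that the method would
identify the true pathway in any particular real trajectory.

## Numerical and design choices

* **Internal unit** is kJ/mol; the converter (factor 4.184 exactly) exists
  because MD engines commonly emit kcal/mol while the reference tables are
  kJ/mol.  Round trips are exact to 1e−9.
* **One table dialect**: long-format TSV, one row per (snapshot, residue),
  `#` comments, rows sortable in any order.  Missing cells are an error —
  the correlation machinery needs complete series; imputation is refused.
* **Pearson on constant series** raises a dedicated `ZeroVarianceError`
  rather than returning a sentinel; correlation matrices carry an explicit
  `defined` mask (undefined entries are NaN + flag, never 0) and undefined
  factors are excluded from networks and pathways with a logged count.
* **Strict inequalities everywhere a threshold is quoted** (`> 10 Å`,
  `> 8 kJ/mol`, `> 5 kJ/mol`, `> 0.5` / `< −0.5`, `C > 0.3`); values equal
  to a threshold are excluded.  The side-chain network uses a *closed*
  cutoff (`distance ≤ 20 Å`), matching the usual contact-graph convention.
* **Threshold filters default to absolute value**: reported responsive
  residues include negative changes (e.g. an electrostatic change of
  −5.134 kJ/mol), so `|Δ| >` is the operative reading; a signed mode is
  available.
* **Start/end states are 10-snapshot window means** (0.5 % of a
  2000-snapshot run) rather than single frames; `window=1` recovers the
  literal reading.
* **The 7×7 term matrix** defaults to pooled 2-D correlation (flatten the
  residue×snapshot matrices and correlate all cells), mirroring a 2-D
  array-correlation routine; a `system_sum` mode (sum over residues per
  snapshot, correlate the length-N series) covers the whole-protein
  reading.  Which axis the original analysis used is not determinable, so
  both are exposed and only sign structure is asserted.
* **Clustering is by connected components** of the thresholded graph.  A
  mutually anticorrelated group cannot be pairwise transitive (if x is
  anticorrelated with y and z, then y and z are positively correlated), so
  component membership — not sign-consistent blocks — is the only coherent
  reading of "clustered with correlation < −0.5".
* **C is signed** and thresholded as `C > 0.3`; two negative factor
  correlations multiply to a positive C.  An `abs` switch covers the
  alternative |C| reading.  The bounds `|C| ≤ |Cor(A,X)|` and
  `|C| ≤ |Cor(X,B)|` hold because each factor is ≤ 1 in magnitude.
* **Superposition** is the proper (det +1) least-squares rigid fit
  (Kabsch, via `scipy.spatial.transform.Rotation.align_vectors`) on the
  backbone-atom mask; collinear or <3-point masks are rejected.  Per-residue
  RMSD uses one *global* fit per frame — residues are measured in the
  frame of the whole molecule, not individually re-fitted.
* **RMSD window** defaults to the trailing 5 % of frames (mean over the
  window); `window=1` gives the final-frame deviation.
* **Side-chain centroids** are means of side-chain heavy atoms, falling
  back to Cα for glycine and for backbone-only models.  The 20 Å default
  cutoff is implemented as specified but is far larger than a typical
  contact cutoff (4.5–8 Å); it should be treated as a permissive
  neighbourhood graph and is configurable.
* **Conservation scores** follow the ConSurf/Rate4Site normalised
  convention (lower = more conserved).  The loader requires the polarity to
  be stated explicitly and refuses to guess; `higher_is_conserved` tables
  are negated on load.

## Problem sizes used in tests and the acceptance script

Study-scale checks (pathway recovery, sign structure, convergence) run the
generator at its default 449 residues × 2000 snapshots over 10–20 seeds;
convergence is additionally checked at 500 and 8000 snapshots.  Unit and
property tests use 40–100-residue, 200–4000-snapshot draws.  These sizes
make the full suite and the acceptance script each complete in well under a
minute while keeping the statistical margins wide (the planted-versus-null
C-score gap at the default conditions is ≈ 0.65 vs ≈ 0.001).

## Known limitations

* The published Table-1-style correlation magnitudes and the residue lists
  of the original study depend on its (unavailable) trajectory; the package
  asserts only the reproducible structure — table totals, sign patterns,
  threshold logic and recovery on planted data.
* Pathways are correlation-membership sets, not graph paths; no
  shortest-path or flow computation is performed over the side-chain
  network.
* Single-chain scope; no multimer alignment, no secondary-structure
  assignment, no free-energy machinery.
* The average conservation of a published seven-residue shared set cannot
  be reconciled with the six published single-mutant scores plus any
  plausible seventh value; the package therefore computes means only over
  explicitly supplied score sets.
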