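# Methods

This note documents the models, algorithms and numerical choices behind
`saxsemble`, and what the synthetic-data experiments do and do not
demonstrate.

## Structural model and conformer pools

A construct is a set of chains tiled by **rigid domains** and **flexible
segments** (1-based, inclusive residue ranges; a per-domain numbering
offset maps construct-local indices to the numbering used by external
data). Rigid domains carry source coordinates and move only as rigid
bodies: every sampled model reproduces the source's internal distances
exactly (up to floating-point rotation error, < 1e-9 Å in practice).
**Tethers** declare that two domains' relative pose is fixed — their
source coordinates are interpreted in one shared frame (as taken from a
crystal structure of the anchoring interface) and the pair moves as one
body. This reflects motif-mediated anchoring (e.g. short linear motifs
bound to a β-propeller) without modeling the motif interaction itself.

Flexible segments are grown as self-avoiding Cα chains: consecutive beads
at the trans-peptide Cα–Cα distance of 3.8 Å, and no non-bonded pair
closer than 4.0 Å (rigid-internal contacts are exempt, since the source
geometry is authoritative there). Growth is outward from placed anchors;
a domain reached through a linker is then placed with a random
orientation at bond length from the final linker bead, clash-checked as a
whole. When both ends of a segment are already fixed (a linker between
tethered bodies), growth proceeds **bidirectionally** from the two
anchors with a feasibility constraint — the gap between the growing ends
may never exceed (remaining bonds)·3.8 Å minus a 0.5 Å closure margin —
and a direction bias toward the far end that strengthens as the chain
becomes taut; the final bead is placed exactly on the circle at bond
length from both neighbours, so closure is exact. Failed beads trigger
segment regrowth (default 100 attempts) before a sampling error naming
the segment is raised. Sampling an ensemble pool this way replaces
physics-based conformer generation: the selection step, not the sampler,
carries the inference, so the pool only needs broad, reproducible
conformational diversity. All randomness flows from a single
`numpy.random.Generator`, making pools bitwise reproducible by seed.

Uniform masses are used for all centroids and radii of gyration: the
analysis is shape-level, where residue-mass weighting shifts Rg by well
under 1% at one bead per residue.

## Scattering

Theoretical curves use the Debye equation over beads,
I(q) = Σᵢⱼ fᵢfⱼ sinc(q·dᵢⱼ), with a constant per-bead scattering length by
default (an optional Gaussian form factor is accepted as a callable).
Excluded-volume and hydration-shell corrections are deliberately out of
scope; at q ≤ 0.5 Å⁻¹ and one bead per residue the shape information that
drives ensemble selection is retained. For large models the double sum is
replaced by a pair-distance histogram whose bins are represented by their
**mean** pair distance (second-order accurate); at the default 0.5 Å bin
the approximation agrees with the exact sum to ~0.2%, and to < 0.1% at
0.25 Å.

- **Guinier fit**: weighted linear fit of ln I vs q², iterated from the
  lowest q until q·Rg ≤ 1.3 (the community-standard window); a
  non-negative slope is reported as a fit failure rather than Rg = 0.
- **P(r)**: regularized indirect Fourier transform on a 101-point r-grid
  with p(0) = p(Dmax) = 0 pinned, a second-difference smoothness penalty,
  and the penalty weight chosen at the maximum-curvature corner of an
  L-curve scan over α ∈ [1e-4, 1e2] (25 log-spaced points) unless fixed
  explicitly. Negative excursions are clipped and the density
  renormalized; the forward-computed χ of the clipped solution is
  reported so over-regularization is visible. Real-space
  Rg² = ∫r²p dr / 2.
- **Dimensionless Kratky**: (qRg)²·I/I(0) vs qRg, peak refined by
  quadratic interpolation; a curve whose grid maximum does not rise above
  the boundary values (flat or monotone transforms, as for an ideal
  chain) reports no interior peak. For the Guinier intensity model the
  peak is analytically (√3, 3/e); the pipeline reproduces (1.73, 1.10) to
  printed precision.
- **Vc / MW**: Vc = I(0)/∫q·I dq, integrated by trapezoid to 0.3 Å⁻¹ by
  default with a convergence warning when q·I has not decayed;
  MW = (Vc²/Rg)/0.1231 Da, the protein calibration of the
  volume-of-correlation method.
- **χ**: reduced and error-weighted,
  χ = sqrt(mean(((s·I_model − I_exp)/σ)²)) with the scalar s fitted by
  weighted least squares. The free scale absorbs intensity
  normalization; χ conventions differ between programs, so this one is
  documented here and used consistently everywhere (values < 1 simply
  mean fitting within the stated errors).

## Sparse ensemble selection

The selector is a beam-search matching pursuit under non-negativity and
sum-to-one. A beam (default width 8) of candidate supports is kept; each
step extends every beam support by every pool member, re-solves
non-negative least squares on the weighted design (the overall scale is
free, so weights are normalized after solving), and retains the best
extensions. The search stops when the best χ improves by less than `tol`
(default 0.01) or the support reaches `k_max` (default 20); accepted
steps therefore descend monotonically in χ. Restarts (default 2) permute
the candidate order, which randomizes the resolution of exact χ ties;
the whole procedure is deterministic given its seed. On pools of ≤ 12
with supports ≤ 3 the beam search matches exhaustive enumeration
(`brute_force_select`, kept as an independent oracle — the two routes
share only the NNLS solver). Members assigned zero weight by NNLS are
pruned, so K counts strictly positive weights.

Derived descriptors: the weighted Rg histogram with its modal bin, the
pointwise weighted average curve, and the weighted fraction of members
whose interdomain centroid distance falls below a cutoff (the
compact-population statistic).

## Cross-links

Cross-links are unordered residue pairs (canonicalized at construction;
self-links rejected) with DSS chemistry assumed: the default satisfaction
cutoff is 30 Å Cα–Cα, reflecting the 11.4 Å spacer plus two lysine side
chains and backbone allowance — the literature-standard bound, exposed as
a parameter and echoed in every report since no universal value exists.
Cα–Cα rather than side-chain nitrogen distances are used because the
models are Cα-coarse. Satisfaction is monotone in the cutoff;
ensemble-level consistency asks whether *some* member with positive
weight satisfies each link, which is the appropriate reading for a
population-averaged measurement and is monotone in the support.

## NMR titrations

Weighted CSPs use Δppm = sqrt(ΔδH² + (ΔδN/5)²); the 1/5 compresses the
¹⁵N axis onto a ¹H-comparable scale. Matching is by assigned residue
index; an assignment-free nearest-peak mode (same metric, 0.05 ppm gate)
exists as an extension for unassigned lists. Interface selection is a
strict threshold on Δppm — thresholds are explicit inputs, since
published analyses choose them case by case. Titration trajectories are
reported relative to the first point with NaN gaps where a residue is
missing (no interpolation).

## Synthetic ground truth

The generator emulates the architecture of the target systems — globular
WD40-like bodies of radius ~18–21 Å joined by 20–50 residue linkers —
with these choices:

- **Domains** are random sphere packings at one bead per 210 Å³ of
  envelope volume. That density was calibrated so the volume-of-
  correlation MW of the bead model matches a sequence mass of 110
  Da/residue, mirroring how a real ~34 kDa β-propeller of Rg 19.8 Å
  corresponds to a sphere of equal Rg at ~227 Å³/residue. Chain termini
  are placed at the domain surface so linkers can be grown outward.
  Lysines are sprinkled at 8% density for cross-link simulation.
- **Two-state truth**: the compact and extended Rg extremes of a seeded
  candidate sample, with populations 0.7/0.3 — well-separated states
  without hand-built coordinates.
- **SAXS noise**: σ(q) = noise·I(q)·(1 + 2q) with one Gaussian draw per
  point (noise 1% by default) on a 160-point grid over 0.006–0.5 Å⁻¹.
  Multiplicative noise with mild q-growth is an explicit, simple stand-in
  for beamline error models, constructed so that the true curve scores
  χ = 1 ± 3/√N against its own realization by definition.
- **Cross-links** sample lysine pairs satisfied in a population-weighted
  true member; an exact count of decoys (pairs violated in *every*
  member) can be planted, so consistency bookkeeping has ground truth.
- **Titrations** follow a 1:1 fast-exchange isotherm (protein 100 µM,
  K_D 5 µM, ratios 0–7, so the end point is ≈99% bound): interface
  residues move by f_bound·Δδ_max with saturating Δppm drawn from
  0.2–0.5 ppm, background residues jitter by σ = 0.005 ppm (¹H).

What passing the recovery experiments shows: the pipeline identifies the
planted members out of 500 same-distribution decoys, recovers populations
to a few hundredths, and flags exactly the decoy cross-links — i.e. the
algorithmic chain is correct and well-calibrated. What it does not show:
robustness to real-data pathologies (inter-particle interference,
concentration effects, hydration-layer contrast, mis-assigned
cross-links, exchange-broadened NMR peaks), since the generator does not
model them. On real data the fitted populations are also only as
meaningful as the pool is representative; the generator guarantees the
true states are in the pool, real applications cannot.

## Problem sizes and defaults

Default experiments use pools of 500 conformers, 160-point curves,
K_max = 10, and 20 seeded replicates for the recovery statistics; tests
use pools ≤ 2000. These sizes were chosen as the smallest at which the
recovery statistics are stable across seeds. Degenerate inputs are
handled explicitly: empty structures, HETATM-only files, flat profiles
(Guinier failure), non-overlapping q-grids, unsatisfiable restraint
minima and infeasible closures all raise typed errors naming the
offending object.

## Known limitations

- No atomistic energetics: linker conformations are excluded-volume-only,
  so linker-mediated contacts (e.g. a disordered tail folding back) are
  sampled but not favored.
- Constant form factors bias absolute intensities at q ≳ 0.4 Å⁻¹;
  comparisons there should be qualitative.
- The L-curve corner criterion for P(r) differs from perceptual-criteria
  programs; Dmax must be supplied (or scanned) rather than auto-detected.
- Beam-search selection is near-exact on small instances but, like all
  matching pursuits, has no global-optimality guarantee on large pools.
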