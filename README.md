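# saxsemble

Sparse ensemble modeling of flexible multidomain proteins from small-angle
X-ray scattering (SAXS), cross-linking mass spectrometry (XL-MS) and NMR
titration data.

Many regulatory assemblies — for instance histone methyltransferase core
complexes built from WD40 β-propellers, a SET domain and long flexible
linkers — are not single structures but dynamic ensembles held together by
several weak interaction sites. Solution methods see such systems as
averages: SAXS measures the rotationally averaged intensity *I(q)* of the
whole population, DSS cross-links report lysine pairs that come within a
bounded distance in *some* populated conformer, and amide chemical shift
perturbations (CSPs) locate binding surfaces. `saxsemble` provides the full
desk-scale pipeline that turns these averaged measurements into an explicit
weighted ensemble of conformers, together with a synthetic-data generator
that makes every stage testable against known ground truth.

## The model

A construct is declared as rigid domains (crystal-structure coordinates,
moved only as rigid bodies; tethered domains share one frame) connected by
flexible segments grown as self-avoiding Cα chains (bond 3.8 Å, clash
cutoff 4.0 Å). For a pool of *n* conformers with theoretical Debye curves

&nbsp;&nbsp;&nbsp;&nbsp;*I<sub>j</sub>(q) = Σ<sub>k,l</sub> f<sub>k</sub>(q) f<sub>l</sub>(q) sin(q d<sub>kl</sub>)/(q d<sub>kl</sub>)*,

sparse ensemble selection (SES) finds few non-negative weights *w* with
Σ*w<sub>j</sub>* = 1 minimizing the error-weighted, optimally scaled misfit

&nbsp;&nbsp;&nbsp;&nbsp;*χ = sqrt( (1/N) Σ<sub>i</sub> ((s·Σ<sub>j</sub> w<sub>j</sub> I<sub>j</sub>(q<sub>i</sub>) − I<sub>exp</sub>(q<sub>i</sub>)) / σ<sub>i</sub>)² )*,

via a beam-search matching pursuit (the beam keeps the best supports at
each size, so small instances match exhaustive search). Primary SAXS
analysis implements the Guinier fit (Rg, I(0)), a regularized indirect
Fourier transform to P(r) with Dmax, the dimensionless Kratky transform
(qRg)²·I/I(0) — whose maximum for a globular particle sits at
(√3, 3/e) ≈ (1.73, 1.10) — and the volume-of-correlation molecular weight
estimate MW = (V<sub>c</sub>²/R<sub>g</sub>)/0.1231 Da. Cross-links are
validated at the ensemble level (a link counts as consistent if at least
one populated member satisfies the Cα–Cα cutoff, 30 Å for DSS), and NMR
titrations are scored with the weighted displacement
Δppm = sqrt(Δδ<sub>H</sub>² + (Δδ<sub>N</sub>/5)²).

## Worked example

`examples/02_ensemble_recovery.py` plants a two-state ensemble (70%
compact / 30% extended) of a two-domain construct with a 30-residue
linker, simulates a 1%-noise SAXS curve, and recovers the states from a
pool of 500 conformers:

```
fit quality chi          : 0.90 (≈1 means fit within the noise)
ensemble size K          : 2 of a pool of 500
true populations         : 0.70 / 0.30
recovered populations    : 0.69 / 0.31
weight errors            : [0.006 0.006]
Rg distribution mode     : 24.0 A (dominant true state Rg 23.2 A)
cross-link consistency   : 100% (every planted link satisfied by >=1 ensemble member)
```

χ ≈ 0.9 says the two-member ensemble reproduces the data to within the
simulated errors; the recovered populations are within 0.01 of the planted
ones; the weighted Rg histogram peaks at the dominant (compact) state; and
every simulated DSS cross-link is satisfied by at least one selected
member. The other examples demonstrate primary SAXS analysis of a globular
domain (`01`), decoy detection in cross-link tables (`03`) and CSP-based
interface mapping (`04`).

A thin CLI wraps the same stages for file-based work:

```bash
saxsemble simulate --seed 5 --out run/        # synthetic truth bundle
saxsemble analyze run/saxs.dat --out run/analysis
saxsemble fit run/saxs.dat run/pool --out run/fit
saxsemble xl-check run/crosslinks.csv run/pool --weights run/fit/weights.csv --out run/xl
```

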