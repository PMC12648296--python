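# Methods

This note documents the models implemented by `excitonscope`, the choices
made where several reasonable conventions exist, and what the synthetic
data do and do not emulate.

## Units and constants

Coordinates are in Å, charges in elementary charge e, energies in eV,
spectra in cm⁻¹ (1 eV = 8065.544 cm⁻¹), and volumetric grids in bohr
following the Gaussian cube convention. The Coulomb constant is carried as
k_e = 14.39964 eV·Å/e² so no SI prefactors appear in the coupling formula.
Dipoles are internal in e·Å and reported in Debye (1 e·Å = 4.80321 D).

## Transition charges and dipoles

Transition charges are atom-centred monopoles aligned 1:1 with a pigment's
atom list (reordering, if needed, happens at load time). The transition
dipole is Σ_I q_I r_I; a uniform rescaling either applies a fixed factor
(default 0.724, used for both BChl and BPh) or matches a target dipole
magnitude. The experimental Q_y dipole target is a configuration input, not
a constant, because the appropriate value depends on the medium correction
adopted; the synthetic generator uses 6.3 D, a standard in-protein
effective value for BChl a.

## Site-energy landscape

Per-pigment trajectories are summarized by the arithmetic mean and the
sample standard deviation (n−1 denominator; the choice matters little at
trajectory lengths of 10³–10⁴ frames but is stated for reproducibility).
The density of states is a histogram on a fixed bin width (default
0.013 eV; a 0.245 eV variant suits small-sample CT scans) smoothed by a
*natural* cubic spline through the bin centres, evaluated on a 10× finer
grid; negative interpolated values are clipped to zero before the curve is
renormalized to unit trapezoidal integral. Environmental shifts are
e_env − e_gas rounded to three decimals, classified as blue (+), red (−)
or neutral (0).

## Exciton Hamiltonian

TrESP couplings are screened Coulomb double sums over atom pairs with a
single constant screening factor (default 0.69) applied to every pair,
including ring↔RC pairs; no distance cutoff is applied by default because
N = 38 is small. Geometries closer than 0.1 Å between two pigments are
rejected as overlapping. Diagonalization uses `numpy.linalg.eigh`
(ascending eigenvalues); exciton dipoles are μ_k = Σ_m c_mk μ_m, which
preserves the dipole-strength sum Σ|μ_k|² = Σ|μ_m|² by unitarity. A
far-field point-dipole formula is provided purely as an independent
cross-check of the Coulomb sum.

## Absorption spectra

The lineshape is the standard second-order cumulant

g(t) = (1/π) ∫₀^∞ dω J(ω)/ω² [coth(ħω/2k_BT)(1 − cos ωt) + i(sin ωt − ωt)]

evaluated by trapezoidal quadrature over the spectral density's own
frequency grid (the ω = 0 point is excluded; the integrand is finite there
for any J that vanishes linearly at the origin, so the omission is
harmless on fine grids). Fluctuations are assumed diagonal in the site
basis and uncorrelated between sites, giving each exciton
g_k(t) = (Σ_m c_mk⁴) g(t) — the participation-ratio approximation. This is
an approximation to full cumulant-expansion treatments: off-diagonal
fluctuation terms and exciton-relaxation-induced lifetime broadening are
neglected. Consequences are correct monomer and high-temperature limits
(tested against the Drude-Lorentz closed form) but potentially
underestimated widths for strongly delocalized states.

The spectrum is the half-Fourier transform
I(ω) = (1/π) Σ_k |μ_k|² Re ∫₀^∞ dt e^{i(ω−ω_k)t − g_k(t)} with a uniform
time grid (default 2 ps, 4096 points) and an exponential damping chosen so
the integrand has decayed to 10⁻⁸ at the final time; with a zero spectral
density each exciton then appears as a narrow Lorentzian of a few tens of
cm⁻¹, i.e. a grid-scale line at its eigenvalue. Small negative excursions
from the truncated transform are clipped to zero, so intensities are
non-negative by construction and integrated-intensity comparisons are made
relatively (to ≈1%), not absolutely. Alignment to an experimental peak is
a rigid translation by 10⁷/λ_nm − peak; no static disorder is added.

## CT-state classification

Classification from NTO descriptors is total and deterministic with
precedence pure_CT > mixed > ME > LE:

* dominant component with single-fragment hole ≠ single-fragment particle:
  **pure_CT** if n ≥ 0.94 and f ≤ 0.01 (boundary values included),
  otherwise **mixed** CT/excitonic;
* dominant component delocalized over ≥ 2 fragments: **ME**;
* otherwise **LE** — including states with two sizeable same-fragment
  components on *different* pigments, which are local excitations
  componentwise. (One packaged reference row lists such a state with
  weights "0.56, 28"; the second weight is read as 0.28, an apparent
  typographical slip, since NTO weights lie in [0, 1].)

The f boundary between ME and mixed character is not sharply defined in
the literature; f > 0.01 is the documented default. Fragment labels may be
composite ("P_M/P_L") to express delocalization within one component.

Voxel→fragment assignment is nearest-atom (Voronoi) via a k-d tree; each
voxel belongs to exactly one fragment, so fragment charges partition the
total grid integral exactly. Ties in distance resolve to the
lower-indexed atom (the k-d tree's stable ordering), a measure-zero
choice. Δρ > 0 means electron gain, so a donor has Δq < 0. The packaged
reaction-centre state table carries a CT state index only where it is
determined by the source data (the 100 ns P_L/B_L snapshot, where the CT
state *is* S₁); elsewhere the index is absent and summaries report index
sets over records that have one. The accompanying text and table disagree
on the P_L/B_L lower bound (1.987 vs 1.983 eV); table-derived values are
reported.

## Koopmans tuning

The default objective is IP-only, J(ω) = |ε_HOMO + IP|; the EA term is
optional. Tuning records describe isolated gas-phase pigments. Ties break
toward smaller ω (stronger long-range correction at shorter range is the
conservative choice for CT states). Selection is order-invariant.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
with exact ground truth:

* **Geometry**: 32 ring pigments at consecutive angles on an ellipse
  (semi-axes 47 × 41 Å) with tangential, same-sense transition dipoles —
  the head-to-tail arrangement that makes nearest-neighbour couplings
  negative (≈ −400 to −500 cm⁻¹ at these spacings) and the low-energy
  exciton superradiant, as in real antenna rings — plus six RC pigments in
  a C₂-symmetric L/M arrangement. Pigments are pseudo-molecules of six
  point charges rescaled to the target dipole; they are sufficient for
  TrESP and grid tests but not chemically realistic, and carotenoids,
  hemes, quinones and the non-heme iron are not generated.
* **Trajectories**: exact-discretization Ornstein-Uhlenbeck series
  (x_{t+1} = μ + φ(x_t − μ) + σ√(1−φ²)ε, φ = e^{−1/τ}), stationary
  N(μ, σ²) with autocorrelation e^{−lag/τ}. Defaults: ring mean 1.877 eV,
  σ = 0.05 eV, 20 000 frames at 10 ps stride, τ = 50 frames. Because
  samples are correlated, mean-recovery tests use the inflated standard
  error σ√((1+φ)/(1−φ))/√n rather than σ/√n.
* **State tables**: records drawn per class so that descriptors satisfy
  the class definitions by construction; truth labels are returned
  alongside.
* **Density pairs**: Gaussian lobes on two fragments 12 bohr apart,
  discretely normalized to exactly 1 e on the grid, so Δρ integrates to
  zero exactly and direction reversal flips fragment charges exactly;
  pure-CT/ME/LE variants carry truth Δq of ∓1, ∓0.5 and 0 e.
* **Spectral density**: analytic Drude-Lorentz 2λωγ/(ω²+γ²) (defaults
  λ = 35 cm⁻¹, γ = 50 cm⁻¹) with optional underdamped vibrational modes,
  standing in for measured spectral densities, which can be supplied as
  two-column tables.

Passing tests on these inputs demonstrate correctness of the analysis
operations and statistical calibration of the estimators; they do not
validate the electronic-structure inputs themselves, conformational
sampling, or non-Gaussian site-energy statistics seen in some real
systems.

## Problem sizes

The test suite and the acceptance script run the full 38-pigment complex
for Hamiltonian/spectrum work, 20 000-frame trajectories for landscape
statistics, and 200-member ensembles for classification and fragment-
charge recovery (density grids 48×24×24 at 0.6 bohr in the ensembles,
64×32×32 at 0.5 bohr in single-pair tests). These sizes were chosen so
estimator noise is far below the tested tolerances.

## Known limitations

* The cumulant lineshape omits off-diagonal fluctuations and interexciton
  relaxation; computed widths are a lower bound for delocalized manifolds.
* CT states are excluded from the spectral model; in real LH1-RC spectra
  they contribute a sizeable part of the red shift, which is why aligned
  spectra require a rigid shift at all.
* Screening of couplings is a single constant; polarizable or
  state-specific environment models are out of scope.
* The cube reader rejects the Ångström (negative voxel count) variant by
  design to keep units unambiguous.
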