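# Methods

`twodir` implements the analysis chain by which a 2D-IR spectrum of a
metal-carbonyl active site — concretely, the CO/CN stretching region of the
[FeFe]-hydrogenase H-cluster in its oxygen-stable inhibited (H_inact) state —
is converted into an intramode/intermode anharmonicity matrix, related to
vibrational mode localization, and used to rank candidate active-site
structures.  This note records the model, the conventions, the tunable
parameters, and the choices made where the design was genuinely open.

## The vibrational ladder and its observables

Five high-frequency oscillators (bridging CO at 1847 cm⁻¹, two terminal COs
at 1982/2007 cm⁻¹, two cyanides at 2087/2107 cm⁻¹) define a ladder of states
with at most two total quanta, labelled |abcde⟩ with one occupation digit per
mode in ascending frequency order.  With fundamentals ν_i, the ladder is
parameterized by a symmetric anharmonicity matrix Δ:

    E(1_i)     = ν_i
    E(2_i)     = 2ν_i − Δ_ii        (intramode anharmonicity)
    E(1_i 1_j) = ν_i + ν_j − Δ_ij   (intermode anharmonicity)

The sign convention is Δ = (0–1 frequency) − (1–2 frequency): positive Δ is
normal anharmonic softening; negative Δ (one observed entry, −3 cm⁻¹) means
a partner excitation stiffens the coordinate.  In a 2D spectrum, Δ_ii is the
probe-frequency gap between a diagonal bleach and its excited-state
absorption (ESA); Δ_ij is the gap between a cross-peak bleach and the
corresponding combination-band sequence transition.

Missing entries are explicit: an anharmonicity never seen as a bleach/ESA
pair is NaN ("unobserved"), not zero.  The bridging-CO/low-terminal-CO
coupling sits below the 1 cm⁻¹ detection limit and is stored as 0 with a
"<1" provenance qualifier; it is excluded from ranking selections.  The
printed peak catalogue rounds positions to integers, so the weak couplings
recomputed from it can differ by 1 cm⁻¹ from values quoted from unrounded
fits; the extraction reports what its inputs give and does not attempt to
reconstruct unrounded positions.

Printed-value comparisons round half away from zero, since positions are
reported as integers.

## Coupled local-mode (vibrational exciton) model

Each ligand stretch is a local anharmonic oscillator, E_i(n) = ω_i n −
χ_i n(n+1), so the uncoupled intramode anharmonicity is exactly 2χ_i.
Bilinear couplings β_ij connect sites under a number-conserving
(rotating-wave) Hamiltonian — standard for CO-stretch excitons and exactly
block-diagonal in total quanta.  The one-quantum block has diagonal
ω_i − 2χ_i and off-diagonal β_ij; the two-quantum block has diagonal
2ω_i − 6χ_i and (ω_i−2χ_i)+(ω_j−2χ_j) with harmonic-scaling off-diagonals
⟨2_i|H|1_i1_j⟩ = √2 β_ij and ⟨1_i1_j|H|1_i1_k⟩ = β_jk.  No cross-site
quartic terms: the only anharmonicity source is χ, the minimal model that
reproduces the localization/coupling trends.

**Eigenstate assignment.**  Two-quantum eigenstates are assigned by maximal
squared overlap with *exciton-product* zeroth-order states — bosonic
two-quantum products of the one-quantum eigenmodes — rather than with the
local basis.  This is the anharmonicity-free reference: for χ = 0 the
exciton products are exact eigenstates and all anharmonicities vanish
identically, and for β = 0 they reduce to the local states.  Assignment
against the local basis would break both limits for coupled near-degenerate
sites.  One-quantum eigenmodes are labelled by their dominant site.
Assignment is greedy in ascending energy over unclaimed states; exact
symmetric ties resolve toward the lower-energy zeroth-order state, and a
genuinely ambiguous assignment (an eigenstate dominated by an already
claimed character by more than the 10⁻⁶ tie tolerance) raises an error
suggesting a symmetry-breaking perturbation.

**Darling–Dennison splitting.**  Near site degeneracy the residual coupling
between exciton-product two-quantum states pushes the overtone of the lower
eigenmode down and the upper one up, making the two intramode
anharmonicities unequal even for identical sites.  `solve_ladder(...,
two_quantum_mixing=False)` replaces the eigenvalues by the deperturbed
diagonal in the exciton-product basis; in the degenerate case this restores
Δ_low = Δ_high (= χ), isolating the resonance mechanism.

The speculative 1–3 resonance with low-frequency modes, proposed to explain
the unusually high 23 cm⁻¹ intramode value of the low terminal-CO mode, is
deliberately not implemented.

## Forward spectrum simulation

A frequency-domain Bloch-limit simulator: signed stick peaks broadened with
2D Gaussians, no time-domain response functions or phase cycling (the
analysis uses only positions and signs).  Ground-state bleach and stimulated
emission merge into one negative peak; ESA magnitude equals the merged
bleach magnitude (harmonic |μ₁₂|² = 2|μ₀₁|² scaling), so for Δ → 0 bleach
and ESA cancel exactly and all contrast comes from positional shifts.
Diagonal amplitudes scale as μ_i⁴·O(0°), cross amplitudes as
μ_i²μ_j²·O(θ_ij), with the isotropic four-wave-mixing orientational average

    O_parallel      = (1 + 2cos²θ)/15
    O_perpendicular = (2 − cos²θ)/15

whose ratio crosses 1 at arccos(1/√3) ≈ 54.7°.  The qualitative statement
that cross peaks gain contrast in perpendicular polarization for dipole
angles "above 45°" is implemented with the standard 54.7° crossover; the
looser 45° figure is not matched.  Cross pairs with |Δ| below a threshold
(default 0.5 cm⁻¹) or unobserved couplings emit nothing.  Dipole-forbidden
double-jump peaks are opt-in with a user-set relative amplitude; the
fifth-order three-quantum feature is never emitted by default.  Defaults:
0.5 cm⁻¹ grid step, 8 cm⁻¹ FWHM.

## Peak fitting and matrix assembly

Pump slices are taken at the grid rows nearest each fundamental
(nearest-neighbour, ties to the lower row) and fitted with a sum of signed
Gaussians plus a constant baseline (nonlinear least squares via lmfit).
Component signs are fixed by their seeds, preventing bleach/ESA identity
swaps; FWHM is bounded to [2, 30] cm⁻¹; center uncertainties come from the
linearized covariance.  Operator-free seeding takes signed local extrema of
a lightly smoothed trace (3 cm⁻¹ Gaussian, below the narrowest physical
linewidth) exceeding 3× the robust noise level (MAD of first differences of
the raw trace) and 1% of the trace maximum.

Assembly classifies negative components as bleaches (assigned to the nearest
fundamental within 10 cm⁻¹) and pairs each positive component with a bleach
inside an asymmetric window: up to 30 cm⁻¹ above the ESA (normal red-shifted
anharmonicity) and 6 cm⁻¹ below it (negative anharmonicity), nearest wins.
A symmetric nearest-neighbour rule would mispair the terminal-CO ESA
ladder, and a strictly-below rule could not recover the negative −3 cm⁻¹
entry.  Strong components claim partners first, so weak artifacts cannot
steal the bleach of a genuine ESA.  Every fitted component appears in an
audit table; unassignable ones are flagged, never dropped.  Entries built
from weak (< 3× noise) or positionally uncertain (> 1 cm⁻¹) components are
marked low-confidence in the matrix provenance — mirroring how the
partially cancelled terminal-CO sequence signal was excluded from the
experimental analysis.  Bootstrap uncertainties are available with an
explicit seed but off by default.

## Normal modes and potential energy distribution

Harmonic frequencies come from the Eckart-projected mass-weighted Cartesian
Hessian (imaginary frequencies reported negative).  The PED uses the Wilson
B matrix of the internal set, the internal force-constant matrix
F = Aᵀ H_cart A with A = M⁻¹Bᵀ(BM⁻¹Bᵀ)⁻¹ (generalized inverse for redundant
sets), and the diagonal convention

    PED(k, mode) = F_kk L_k² / Σ_k' F_k'k' L_k'²,

which keeps fractions interpretable on [0, 1] at the price of row sums
deviating from 1 for strongly coupled coordinate pairs — deviations beyond
±0.05 are flagged, not hidden.  Hessians are accepted in hartree/bohr² or
mdyn/Å, declared in a mandatory file header; there is no unit autodetection.
PED is harmonic-only; bends use standard s-vectors but are not needed for
the CO/CN stretch use case.

## Trends and ranking

Across candidate models, the intramode anharmonicity of a mode follows a
positive-curvature parabola in its localization fraction (minimum in the
delocalized 50/50 limit) and relates negatively to the intermode
anharmonicity.  Candidates are ranked by weighted RMSD (cm⁻¹) to the
experimental matrix over a selection of entries; the default selection is
the terminal-CO block {Δ_low,low, Δ_high,high, Δ_low,high} with unit
weights, because those observables vary strongly with structure while the
bridging-CO and cyanide diagonals are robustly reproduced by all first-
coordination-sphere models and carry no discriminating power.  The RMSD
rule is this package's explicit choice — no quantitative scoring rule is
published — and no statistical significance is attached to rankings.
Entries the experiment does not observe are dropped from the selection with
a log note; ties break by candidate id.

## Synthetic data: what it emulates and what it does not

The generator produces the five-mode preset (printed fundamentals and
anharmonicities), rendered 2D spectra with optional seeded additive Gaussian
noise and an optional diagonal scatter ridge, and seeded local-mode
ensembles (default 23 members, detuning −35..35 cm⁻¹, coupling 4..18 cm⁻¹,
χ = 12.5 cm⁻¹ about a 1994.5 cm⁻¹ center) emulating a structural-model
series with one designated ground-truth member whose matrix doubles as the
pseudo-experimental target (unperturbed by default, so self-consistency is
exact).  Dipole magnitudes (1.3 terminal CO, 1.0 bridging CO, 0.9 cyanide)
reproduce the familiar relative band intensities; dipole angles (0, 60,
120, 175, 90 degrees) put every observed cross pair above the 54.7°
crossover.  The ill-defined terminal-CO sequence signal is generated from
the ladder like any other peak; its partial cancellation by the neighbouring
bleaches emerges in rendering.  Every artefact ships with a machine-readable
truth sidecar, and identical seeds give byte-identical files.

Not emulated: waiting-time dynamics, spectral diffusion, vibrational
lifetimes, detector artefacts, solvent background, or minor contributions
from other redox-structural states.  Passing round-trip tests therefore
demonstrates correctness of the extraction arithmetic and fitting machinery
under idealized Gaussian lineshapes — not robustness to the full complexity
of measured spectra.  Under 5% additive noise the faint cyanide diagonal
peaks (relative 2D amplitude (0.9/1.3)⁴ ≈ 0.23) fall below the 3σ detection
threshold and are reported as unobserved rather than fitted badly; that is
the intended behaviour of the detection logic, and it means the noisy
round-trip validates accuracy only for the entries the pipeline itself
declares confident.

## Numerical choices and problem sizes

Double precision throughout; symmetry tolerances 10⁻⁹ (anharmonicity
matrices, couplings), 10⁻⁸·‖H‖ (Hessians); assignment tie tolerance 10⁻⁶;
peak-pairing pump tolerance 0.5× the 2.8 cm⁻¹ pump resolution.  The
localization sweep uses 21 symmetric detuning points at fixed coupling; the
ranking ensemble 23 members; the Monte-Carlo fit check 100 seeded noisy
realizations of an isolated peak.  Rendered test spectra cover the full
five-mode region at 0.5 cm⁻¹ step (≈ 690×690 points), which keeps a full
simulate-fit-assemble cycle at a few seconds.

## Known limitations

* The anharmonicity matrix is a parameterization of the ≤2-quantum ladder,
  not a potential-energy-surface fit; no wavefunctions are computed.
* The local-mode model omits Fermi and higher Darling–Dennison resonances
  with modes outside the CO/CN set; it cannot reproduce the 23 cm⁻¹
  intramode outlier that such a resonance would explain.
* The diagonal-F PED convention under-reports strongly coupled coordinate
  pairs; row-sum flags signal when that matters.
* Slice fitting is 1D (per pump row); no simultaneous 2D lineshape fitting
  or nodal-line analysis.
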