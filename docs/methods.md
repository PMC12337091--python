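# Methods

## Scope and model

`forsternet` implements a site-based, semiempirical Förster model of
excitation-energy transfer (EET) in pigment–protein antenna complexes,
extended with excitonic Hamiltonians and a Lambert–Beer absorption layer.
The electronic structure is deliberately coarse: each pigment contributes
one effective state per band (Q and B/Soret; a single bright band for
carotenoids), transition dipoles are point dipoles pinned to structural
axes, and the protein environment enters only through a scalar refractive
index and additive site-energy shifts. This is the cheapest model that can
ask whether upper-band ("anti-Kasha") EET can compete with ultrafast
internal conversion; it deliberately biases *against* EET (point dipoles
underestimate chlorophyll couplings relative to transition-density
treatments, and the default B-band IC lifetime sits at the fast end of the
reported range).

## Geometry conventions

Pigment centres: the Mg coordinate for chlorophylls; the unweighted
centroid of the conjugated carbon atoms for carotenoids (all carbons have
equal mass, so centroid = centre of mass). The conjugated-atom list is
configurable per subtype; in the absence of a list, every carbon of the
residue is used. Transition-dipole directions are unit vectors between two
named atoms per (class, band). The shipped defaults (Q_y along NB–ND,
B_x along NA–NC, carotenoid bright state along the polyene chain) are
documented placeholders following the usual Gouterman orientation; any
curated axis table can be loaded from delimited text and takes precedence.
Structures are used in the deposited frame (Å); no superposition or
symmetry expansion.

## Couplings

V_ij = C_dip κ |μ_i||μ_j| / (n² R³), with μ in Debye, R in nm, and
C_dip = D²/(4πε₀·nm³·hc) ≈ 5.034 cm⁻¹ nm³ D⁻² derived from scipy's CODATA
constants at import time (covered by a first-principles unit test at
1e-10 relative). n defaults to 1.4. κ = û_i·û_j − 3(û_i·r̂)(û_j·r̂) is
bounded in [−2, 2]; V is even under a joint sign flip of both axes, so the
arbitrary sign of an axis-atom ordering cannot leak into rates (k ∝ V²).

Class-pair summaries average |V| over all cross-pairs of the full assembly
and multiply by the multimeric order q (1 for monomers; 3/4 for
trimers/tetramers), which compensates the many near-zero inter-subunit
pairs and makes q-mer values comparable to monomers. On q mutually silent
copies of an n-site monomer this scaling obeys the exact identity
avg_scaled = avg_mono · q(n−1)/(qn−1), which the tests assert. Bar-style
reports use |V| (signed mode is retained as a diagnostic); the standard
error uses the number of contributing pairs.

## Overlap density and rates

ρ is computed as ∫ā(ν̃)F̄(ν̃)dν̃ over the intersection of supports at the
finer grid spacing, where ā, F̄ are the acceptor absorption and donor
emission line shapes area-normalised in the wavenumber domain (units of ρ:
cm). Wavelength-axis inputs are converted pointwise (shape-only); for
bands with σ/ν̃₀ of a few percent the difference against a
per-wavelength-density treatment is O((σ/ν̃₀)²) and immaterial. A
λ⁴-weighted wavelength-domain overlap ratio is available as a diagnostic
(`lambda4_overlap_ratio`) but does not enter rates — its units (length⁴)
are incompatible with the rate kernel. Disjoint supports yield ρ = 0 with
a warning rather than an error, since a zero rate is physically meaningful.

k_FRET = 4π²c V²ρ is the wavenumber-domain realization of the golden rule
2π/ℏ|V|²ρ (substituting V[J] = V[cm⁻¹]hc and ρ[1/J] = ρ[cm]/hc); a test
checks both routes agree to 1e-10 relative. With V = 38 cm⁻¹ and
ρ = 450.05·10⁻⁶ cm this gives ≈769 ns⁻¹.

ρ is evaluated once per ordered (donor class, acceptor class, band) and
shared across site pairs — class-level spectral granularity; per-site
spectra are out of scope. Where a class lacks band-specific spectra
(carotenoids), its single bright band is used. Missing measured emission
(e.g. Soret emission) can be approximated by shifting — optionally
mirroring about the 0–0 peak — the absorption line shape
(`approximate_emission`); the default is mirror off with a configurable
per-class Stokes shift.

Efficiencies are branching ratios E = Σk_FRET/(Σk_FRET + Σ1/τ_IC). Default
lifetimes: τ_Q = 6.3 ns (all chlorophyll classes), τ_B = 100 fs for
chlorophyll B→Q (fast end of the reported 100–250 fs, biasing against
EET), 150 fs for the carotenoid bright state and 10 ps for its relaxed
state. All are config-overridable.

## Dipole strengths from spectra

|μ|² = C_cal/n · ∫ε(ν̃)/ν̃ dν̃ over a band window, with
C_cal = 9.186·10⁻³ D² per unit of the dimensionless extinction integral —
the standard integrated-absorption relation, pinned once as a documented
calibration constant. The synthetic library inverts this relation to set
its extinction amplitudes, so the round trip (library → extinction →
dipole) recovers each class's assigned dipole and is asserted in tests.

## Excitons

H has site energies on the diagonal (class band maximum + per-site shift;
shifts beyond ±0.1 eV trigger a warning, not an error; a missing B shift
falls back to the site's Q shift) and couplings off it. Carotenoid entries
in H_B use the low-energy peak of the bright band; in H_Q they use that
value minus 0.8 eV, an estimate of the strongly relaxed emissive state.
Carotenoid participation in H_Q is optional and on by default — it likely
overstates Crt mixing in the Q window and can be disabled per run
(`crt_in_q`).

Diagonalization uses `numpy.linalg.eigh`. Reports are made deterministic
by a fixed convention: each eigenvector's largest-magnitude coefficient is
positive, and (numerically) degenerate eigenvalues are ordered by the
index of their leading-weight site. Weights are squared coefficients; the
weight matrix is doubly stochastic to tolerance because eigenvectors are
orthonormal. Delocalization is IPR⁻¹ = 1/Σc_i⁴ ∈ [1, N]; "exciton on
pigment" assignments use a configurable threshold c_i² ≥ 0.1.

Configuration experiments keep every site's geometry and axis atoms and
swap only the spectral identity (site-energy source, dipole magnitude,
overlap class, IC lifetime): WT, ALL_CHL_A (accessory chlorophylls →
chlorophyll a), NO_CRT, and both. The substitution direction is
configurable because accounts of this experiment differ between
"a→b" and "b→a" framings; the shipped default homogenizes *to*
chlorophyll a, which is the direction with the clean interpretation
(homogeneous site energies → more delocalized excitons).

## Lambert–Beer layer

A(λ) = f_cl Σ_g n_g ε_g(λ) with integer class counts and a single
dimensionless concentration×path knob f_cl; no molar units are claimed.
The default f_cl puts the wild-type peak absorbance near 1 — the regime
where contributions neither vanish nor saturate. Absorbed photons
P = ∫I(λ)(1−10^(−A))dλ; because of the exponential, per-class differences
are *not* additive, and reports always carry the absolute WT score next to
the relative contributions. Contribution of class g is
[P(WT)−P(variant)]/P(WT), with the variant removing g for carotenoids
(added pigments in vivo) and substituting chlorophyll-a counts for
accessory chlorophylls (replacement pigments). Windows default to
350–800 nm (full) and 350–500 nm (Soret). Depth scenes attenuate the
surface flux by I·exp(−K(λ)z).

## Synthetic fixtures

The generators emulate the *structure* of the real inputs, not their
numbers: seeded rejection-sampled pigment positions with a minimum
inter-centre distance in a cubic box, orthogonal Q/B axis-atom pairs,
Gaussian bands in the wavenumber domain. Shipped band parameters (class →
peak nm / σ cm⁻¹ / Stokes cm⁻¹ / dipole D): Chl a Q 662/230/140/6.45 and
B 430/750/900/12.9; Chl b Q 645/230/140/4.8 and B 455/800/900/9.6; Chl c1
Q 630/230/140/3.5 and B 460/800/900/11.0; Crt single band
490/1300/2000/13.0. These encode the orderings the model's qualitative
conclusions rest on — Soret extinction above Q, B dipoles ≈2× Q (hence B
couplings ≈4× Q), accessory-chlorophyll and carotenoid B bands red-shifted
against chlorophyll a (the B-band energy-sink ordering), Stokes-shifted
emission making ρ downhill-asymmetric. They were chosen once as a
realistic caricature and are not fitted.

Two named fixtures ship: `CP24_LIKE` (11 Chl a + 3 Crt), the inventory of
the worked ten-acceptor efficiency example, and `LHC_MIMIC`
(8 Chl a + 3 Chl b + 3 Crt), the default study system — substitution
variants and per-class contributions need accessory chlorophylls to be
non-trivial. Box 45 Å, minimum distance 12 Å, seed 2024. Irradiance is a
normalized 5800 K blackbody photon flux on 300–850 nm; the depth scene
applies a toy attenuation K(λ) = 0.015 + 0.25((λ−350)/450)³ m⁻¹, rising
toward the red as in natural water columns.

What passing on these fixtures does **not** show: agreement with any real
complex's coupling or ρ matrices, real carotenoid spectral shapes
(vibronic structure is absent), or real irradiance. Those require
deposited structures, measured spectra and a curated axis/shift table,
which the same pipeline accepts through its file interfaces.

## Numerical choices

Energies in cm⁻¹ internally (8065.544 cm⁻¹/eV for config values in eV);
distances Å at the structure level, nm inside the coupling kernel; rates
in ns⁻¹. Integration is trapezoidal throughout; common grids are support
intersections at the finer spacing. Interpolation is linear with clipping
at zero. Spectrum containers enforce strictly increasing grids and
non-negative finite values at construction. Problem sizes are small
throughout (≤14 sites, ~10³-point grids), so the full test suite and the
acceptance script each run in seconds.

## Known limitations

No multichromophoric/generalized Förster, transition-density or Dexter
couplings; no vibronic line shapes or site-specific spectra; no
excited-state dynamics (rates and branching ratios only, no master
equation); no spatial delocalization metric beyond IPR⁻¹; the Lambert–Beer
layer ignores radiative transfer and packaging effects. The Q-band
carotenoid state is a crude −0.8 eV heuristic and its Hamiltonian
participation is best treated as an upper bound on Crt mixing.
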