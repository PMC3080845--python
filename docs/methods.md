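# Methods

## The analysis model

The package treats a protein's conformational heterogeneity as a population
distribution over snapshots of a Boltzmann-sampled ensemble. All stages
operate on a `ConformerEnsemble` (frames in Å, shared atom table) and a
`Topology` of fixed per-atom physical parameters. Units are fixed
package-wide: kcal/mol, Å, ns, K, elementary charges;
k_B = 0.0019872041 kcal/(mol·K), k_e = 332.0636 kcal·Å/(mol·e²).

**Dimensionality reduction.** PCA is performed on the Cartesian Cα
coordinates of a pre-aligned reference ensemble using the population
covariance (1/n normalisation — this scales eigenvalues but not their
percentages). Components are reported with eigenvalue percentages summing
to 100. Projections are plain inner products of mean-centred flattened
coordinates with the component vectors; maps and substates live in the
(PC1, PC2) plane.

**Population maps.** A map is a weighted histogram on a regular grid
(default cell 0.4 Å for free/bound maps, 0.6 Å for reweighted maps),
normalized to total mass 1. Optional smoothing applies a 1-cell Gaussian
pre-filter (suppressing counting noise) followed by bicubic spline
interpolation onto a 4× finer grid, clipping at zero and renormalising.
The spline order and the pre-filter are package choices; only "spline
interpolation" is inherited from the analysis tradition. Difference maps
are signed and sum to 0; convex mixtures stay normalized. Substates are
local maxima (8-neighbourhood) above `min_peak_fraction` (default 0.10) of
the global maximum; maxima closer than `min_separation` (default 1.0 Å)
merge into the denser one, because at finite sampling a flat peak top
otherwise splits. Labels S1, S2, … follow PC1 order; substate-average
structures average all frames projecting within `radius` (default 0.3 Å)
of a mode.

**Structural statistics.** Superposition is Kabsch (SVD with determinant
correction). The residue-wise profile measures, for each target structure,
the Cα–Cα distance per residue against its closest ensemble conformer
(closest = minimum overall superposed Cα RMSD; distances taken in that same
global superposition, not per-residue local fits) and pools them as
rmsd_k = sqrt(mean_i d_{i,k}²) — the average runs over targets, the root is
taken after. Closest-conformer ties break to the lowest frame index; a
`stride` argument supports thinning experiments, for which the minimum
RMSD is provably non-decreasing in the stride.

**Principal-mode kinetics.** C(t) is the mean-subtracted autocorrelation
with the unbiased (n−t) normalisation (so the alternating-series hand value
C(1 step) = −1 holds exactly), C(0) = 1 by construction, computed by FFT.
Relaxation models: `exp2` with amplitudes (a, 1−a); `expN` with amplitudes
on the unit simplex; `stretched` = a₁·exp[−(t/τ₁)^β] + a₂·exp(−t/τ₂) +
a₃·exp(−t/τ₃) with the stretch on the fastest term. The simplex/positivity
constraints are enforced by an internal softmax/log re-parametrisation;
fitting is seeded 20-start Levenberg–Marquardt with log-uniform τ
initialisations, deterministic for fixed seed. The placement of β on the
fastest term is an inference from the ordering of printed parameter sets in
the literature this analysis follows, not a unique choice; it is flagged
here deliberately.

For long noisy correlation tables two estimator refinements exist:
`lag_spacing="log"` (fit ~80 geometrically spaced lags, balancing the
decades of a multi-timescale decay) and `weighting="bartlett"` (generalised
least squares with the Bartlett-formula covariance of the autocorrelation
estimator, evaluated under the model from an initial uniform fit and
iterated once, including the O(1/N) downward bias of C(t) caused by
in-sample mean subtraction). These matter: for a two-timescale process with
τ_slow ≈ 13 ns observed for 10 µs, the realized slow correlation time
itself fluctuates with ≈5% standard deviation (the information limit
√(2τ/T)); uniform least squares over 10⁴ linear lags roughly doubles that
dispersion, while the GLS protocol stays near ≈7% and unbiased. Fitted
slow-time values for independent seeds therefore scatter several percent
around the generating value — this is sampling dispersion, not estimator
error.

**Interaction energy.** Only inter-molecular terms are evaluated — for
rigid molecules the intra-molecular energies cancel exactly in the
reweighting energy difference. Electrostatics is Coulomb with interior
dielectric ε_in = 1; dispersion is 12-6 Lennard-Jones under
Lorentz–Berthelot combination; solvent screening is a Still-type
generalized Born term with fixed per-atom Born radii from the topology,
f_GB = sqrt(r² + RᵢRⱼ·exp(−r²/4RᵢRⱼ)) and prefactor −(1/ε_in − 1/ε_w)
(ε_w = 78.5). Because each inter-molecular pair is counted once, the
prefactor carries no ½ (that factor belongs to double-counted self-energy
sums); with it, elec + gb correctly approaches the fully screened
k_e·q₁q₂/(ε_w·r) limit at large separation. Fixed (conformation-
independent) Born radii are a documented simplification; the `EnergyModel`
contract admits a conformation-dependent replacement. No cutoff by
default; atoms closer than 0.1 Å flag a clash and have their distance
clamped (capping the energy).

**Reweighting.** For each approach distance the rigid ligand is translated
from its bound pose along the interface normal (least-squares plane through
protein–ligand contact midpoints within 5 Å, oriented away from the
protein). Snapshot weights follow the Boltzmann ratio of the
inter-molecular energy at the scan distance versus at the 1000 Å
reference position (evaluated explicitly, not set to zero, so any model
artifacts cancel symmetrically), overflow-guarded by subtracting the
minimum energy difference. Weights normalize to 1 by construction; the
Kish effective sample size 1/Σp² is logged per distance and a warning
fires below 1% of n. Decomposition weight sets (polar = elec + gb;
apolar = vdw) multiply, after normalisation, to the total weights —
exactly, since the energy is a sum. Alternative approach directions are
generated by rotating the interface normal about a user axis.

**RDC validation.** Bond-vector second-order terms (the reduced 5-vector
basis [u_y²−u_x², u_z²−u_x², 2u_xu_y, 2u_xu_z, 2u_yu_z]) are averaged over
frames first; one alignment tensor per medium is then fitted by linear
least squares, and Q = rms(D_calc − D_exp)/rms(D_exp). The convergence
curve refits the tensor per contiguous non-overlapping window of each
size — per-window fitting is a package choice where a global-tensor
alternative would also be defensible. Pseudo-bonds between consecutive Cα
atoms serve as bond vectors for Cα-only toys; records whose atoms are
missing are skipped with a warning.

## The synthetic study conditions

The generators stand in for molecular-dynamics trajectories and define the
default conditions every test runs under.

**Toy protein.** Five beads on a short helix; conformational free energy is
a Gaussian-mixture landscape E(x) = −kT·ln Σ_b exp(−E_b(x)/kT) over
harmonic basins E_b = ½Σ_k k_bk(x_k−c_bk)² + depth_b. The mixture form is
chosen deliberately: the equilibrium density is then exactly a mixture of
Gaussians, so substate populations have closed forms and the reweighting
can be validated against an analytic oracle rather than against another
simulation. (The landscape acquires a benign T-dependence through the
mixture; all analyses run at fixed T = 300 K.) The `"ubiquitin-like"`
preset has three basins of near-equal depth (offsets 0.06/0.0/0.12
kcal/mol) separated by 4 Å along one pincer-like collective coordinate
(the terminal beads moving in anti-phase), soft (0.3 kcal/mol/Å²) along
the two pincer coordinates and stiff (2.0) elsewhere. At 300 K this yields
within-basin widths of ≈1.4 Å against 4 Å spacing: three clearly resolved
but exchange-coupled substates whose populations are near-equal, with the
basin-spanning coordinate dominating PC1 — the qualitative structure of a
small protein's free-energy landscape with a dominant collective mode. The
inter-basin barriers are package constants (≈0.3 kT at the saddle), chosen
for reliable Metropolis mixing, not a claim about any real protein.

**Sampling.** Metropolis Monte Carlo with global isotropic Gaussian
proposals (default step 0.25 Å per coordinate, acceptance ≈0.4 on the
preset), burn-in 10% of the requested samples, thinning 1. The default
free-state ensemble is 2×10⁵ snapshots — enough that the three-substate
structure of the smoothed 0.4 Å map is unambiguous while the whole
workflow stays in seconds. All generators take a mandatory seed
(numpy `default_rng`), recorded in ensemble metadata and run reports;
outputs are bit-reproducible.

**Time series.** The two-timescale benchmark is a sum of independent,
exactly discretized stationary OU processes: variance fractions 0.49/0.51,
correlation times 0.4/12.9 ns, 10⁶ steps at 10 ps. Its population
autocorrelation is exactly Σaᵢe^(−t/τᵢ), so fit recovery is a pure test of
the estimator; the residual dispersion quoted above sets what "recovery"
can mean for a single realization.

**Toy ligand and approach.** A rigid 3-atom cluster with charges summing
to a prescribed net charge (+1 e default), placed bound against the first
pincer bead and scanned over 9/12/15/18 Å. Under GB screening a toy of
this size produces a small (fraction-of-a-percent) but strictly monotone
population shift toward the ligand-proximal substate — the mechanism, at
toy magnitude. The 1D two-basin system with an exactly linear field is the
quantitative validation route: reweighted substate populations agree with
the closed-form Gaussian-integral oracle to within Monte-Carlo error.

**What the toys do not emulate.** No excluded volume or chain
connectivity, no rugged intra-basin substructure, no conformation-dependent
Born radii, no ligand flexibility or rotational averaging, and no
experimental noise models beyond additive Gaussians on RDCs. Passing tests
therefore demonstrate the correctness of the estimators and of the
statistical mechanics, not force-field accuracy on real proteins.

## Numerical choices and degenerate inputs

- Covariance 1/n; components from SVD of centred data (no explicit
  Gram matrix), eigenvalues clipped at −1e−12 by construction.
- Histogram grids align cell centres to the data minimum; analyses
  comparing maps across weightings share an explicit grid extent.
- Substate-free maps (no maxima above threshold) return an empty list;
  substate averaging with no members raises, suggesting a larger radius.
- Metropolis with zero acceptance warns with diagnostics; a flat (zero
  stiffness) basin is legal and accepts every move.
- Ragged multi-model PDB files are rejected naming the offending model;
  coordinates beyond the fixed-width PDB field are rejected on write.
- Fits: `lm` with xtol=ftol=gtol=1e−14; ties in multi-start resolved by
  strict cost improvement, so fixed seeds give identical results.
- Reweighting subtracts min ΔE before exponentiation; weights with
  Σp = 1 within 1e−9 are enforced at the dataclass boundary.

## Problem sizes

Default analyses use 2×10⁵ Metropolis snapshots, 10⁶-step series, 1e5-
sample oracle comparisons, and ≤50-atom energy systems; these sizes give
each statistical check ≥3σ resolution while keeping any single stage under
a few seconds on one core.

## Known limitations

- The residue-wise profile is O(targets × frames) with a Python-level
  Kabsch per pair; thin the ensemble (the `stride`/`target_stride`
  options) for large inputs.
- One alignment tensor per medium assumes a single alignment frame over
  the averaging window.
- `find_substates` operates on the (possibly smoothed) grid; peak
  positions are quantised to the fine-grid resolution.
- The interface normal assumes a roughly planar contact patch; strongly
  wrapped interfaces would need a curated direction.
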