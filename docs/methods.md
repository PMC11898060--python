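# Methods

## Cremer–Pople puckering coordinates

For a six-membered ring with positions r_j (j = 0..5), displacements z_j
are taken perpendicular to the mean plane through the geometric center,
with the plane normal defined by the cross product of the sine- and
cosine-weighted position sums. The puckering state is

    q2 cos φ =  sqrt(2/6) Σ_j z_j cos(4πj/6)
    q2 sin φ = −sqrt(2/6) Σ_j z_j sin(4πj/6)
    q3       =  (1/√6)    Σ_j z_j (−1)^j
    Q = sqrt(q2² + q3²),  θ = atan2(q2, q3)

The ring is walked **O5, C1, C2, C3, C4, C5** with O5 at index 0. Under
that convention the ⁴C₁ chair of an α-D-pyranose sits at the north pole
(θ = 0) and ¹C₄ at the south pole, matching the dominant glycoscience
layout of the puckering sphere. The azimuth origin is fixed by the
formulas above; a `--phi-offset` option exists in case external data
follow a rotated convention. Angles are degrees at every public
interface and radians internally.

When Q < 1e−4 Å (below coordinate noise) the ring is flagged planar and
θ/φ are reported as undefined rather than raising.

**Inverse map.** The inverse places a regular hexagon of the requested
bond length in the plane, oriented so that the decorated ring's mean
plane normal is exactly +z, and adds

    z_j = sqrt(2/6) q2 cos(φ + 4πj/6) + (1/√6) q3 (−1)^j.

Because the in-plane lattice sums leave the normal exactly +z and the
center at the origin, the forward map recovers the target to machine
precision — no iteration, no tolerance stacking. Targets whose
displacements would push a ring-walk bond outside 1.2–1.8 Å are rejected
as geometrically infeasible (for a 1.52 Å template this admits Q up to
≈ 0.8 Å; real pyranoses sit near 0.5–0.6 Å).

**Canonical conformer table.** The 38 reference points are derived, not
transcribed: a single displaced atom k yields the envelope ᵏE at
θ = atan√2 ≈ 54.74° (k even; atom-below and southern forms follow by
antipodal symmetry) and φ = −120k mod 360; an adjacent up/down pair
yields a half-chair at θ = atan(√6/2) ≈ 50.77°; pure q2 patterns give
boats at even multiples of 30° of φ and skew-boats at odd multiples.
Classification is nearest-reference by great-circle distance with ties
broken by fixed table order. This reproduces the expected neighborhoods
(E₅ at φ = 300° flanked by ⁴H₅ and ᴼH₅; ¹S₃ at the equator at φ = 210°).

**Reactive partition.** The reactive (catalytically competent) region is
everything strictly north of a boundary polyline θ_b(φ); the default is
the equator with boundary points owned by the nonreactive side. The true
boundary in glycosidase work is drawn through transition-state-mimic
conformations and is not a parallel of latitude, so the polyline is
fully configurable (periodic linear interpolation between knots); the
equator is the defensible default because it separates E₅ (reactive)
from ¹S₃ (nonreactive).

## Free-energy surfaces from hills

A HILLS record k carries a center s_k, widths σ_k, a height w_k and a
bias factor γ. The accumulated bias is

    V(s) = Σ_k w_k exp(−Σ_i Δ_i²/(2σ_{i,k}²)),

with Δ_i the minimum-image difference on periodic axes. Two height
dialects exist in the wild: most engines store the already-damped
(tempered) heights, for which F(s) = −γ/(γ−1) V(s) (the default);
pre-scaled files use F = −V (`dialect="scaled"`). Surfaces are shifted
so the global minimum is zero. The default puckering grid is 144 (φ,
periodic, endpoint excluded) × 72 (θ, bounded, endpoints included).

The instantaneous estimate fluctuates by O(kT) late in a tempered run;
`reconstruct_fes_averaged` therefore averages min-shifted estimates at
(default) 8 checkpoints over the last half of the deposition history.
This is the estimator the pipeline and the barrier-recovery checks use.

**Region free energies and ΔG_r/nr.** A region R is aggregated as
G(R) = −kT ln Σ_{s∈R} e^(−F(s)/kT) ΔA with the uniform node area element
ΔA (the 2D-projection treatment; no sin θ Jacobian, matching how such
surfaces are plotted and integrated in this field). ΔG_r/nr =
G(reactive) − G(nonreactive) at kT = 0.596 kcal/mol (300 K) by default;
a minimum-to-minimum mode is also reported since the statistic's exact
aggregation is a modeling choice — both share the sign convention that
negative favors the reactive region, and on equal-area two-state
surfaces they agree exactly.

## Minimum free-energy paths

On a 2D grid with 8-connected moves (periodic wrap where an axis is
periodic), the path criterion is lexicographic: minimize the maximum
node free energy, then the accumulated sum, then the node count. All
three components are monotone under path extension, so a label-setting
Dijkstra with the composite key is globally exact and deterministic; the
tie-breaks remove the arbitrariness that pure minimax leaves on plateaus.
Node energies only — no diagonal interpolation.

Basins are strict local minima filtered by persistence: a basin's depth
is the free energy of the lowest saddle connecting it to any deeper
basin minus its own minimum (computed by flooding nodes in ascending
order with union–find); the global minimum has infinite depth. The
default depth threshold of 1 kcal/mol suppresses reconstruction-noise
minima.

ΔG‡ = max F − F(start), ΔG = F(end) − F(start), with the transition
state at the first maximum and a ±1-node window quoted as its grid
uncertainty. Observable profiles along a path assign each frame to its
nearest path node in CV space and average within arc-length bins
(default 0.2 CV units); empty bins are flagged, never interpolated.

## Reaction-coordinate geometry

CV1 = d1 − d2 and CV2 = d3 − d4 with d1 the distance from the acid/base
carboxylate oxygen midpoint to the transferred proton H_a, d2 from H_a
to the glycosidic oxygen O_g, d3 from O_g to the anomeric carbon C1′,
and d4 from C1′ to the nucleophile carboxylate oxygen midpoint. The
"center of mass" of two identical oxygens is their midpoint. CV1 < 0
while the proton still sits on the donor and > 0 after transfer; CV2
moves from negative (glycosidic bond intact) to positive (covalent
intermediate formed). Atom resolution goes through configurable
MDAnalysis selections because deposited PDB naming for substrates and
protonated carboxylates varies; a dry-run resolver prints what each
selection matched before any analysis is attempted.

## SASA and the substrate-positioning index

Shrake–Rupley with a deterministic golden-angle (Fibonacci) point set —
no RNG, so areas are bit-stable across runs. Defaults: probe 1.4 Å, 960
points per sphere, Bondi-style van der Waals radii keyed by element
(configurable); a united-atom option drops hydrogens and inflates heavy
atoms by 0.2 Å, otherwise hydrogens occlude explicitly. Group areas
(substrate, pocket) are summed from per-atom areas computed in the
context of the **full** structure — every atom occludes — because the
positioning index contrasts pocket openness with the substrate bound.
SPI = SASA_sub / SASA_pkt, reported per frame with mean and spread over
trajectories; a zero pocket area is reported as degenerate rather than
dividing.

At 960 points the two-sphere error against a 10⁶-point oracle is below
0.2% of the full sphere area; 960 vs 4096 points differ by < 0.5% on the
toy-complex suite.

## Synthetic ground truth

The sampler is overdamped Langevin **in CV space** — the minimal
dynamics that exercises well-tempered bias deposition with a known
answer; it models no molecular system. Update rule:

    s ← s − (Δt/ζ) ∇(U + V_bias) + sqrt(2 kT Δt/ζ) ξ

on the puckering-like domain (φ periodic on [0, 2π), θ reflective on
[0, π]). Every `pace` steps a Gaussian of height
w₀ exp(−V_bias(s)/((γ−1) kT)) is deposited. Defaults mirror a
well-tempered puckering protocol: w₀ = 0.75 kcal/mol, σ = 0.1 rad,
γ = 15, pace 75 steps, kT = 0.596 kcal/mol, and a stop rule that ends
the run once the implied free-energy range γ/(γ−1)·(max − min of the
accumulated bias over the domain) reaches 14 kcal/mol. The raw maximum
of the bias grows logarithmically forever in a tempered run, so the
stop rule uses the max–min range, which plateaus at (1 − 1/γ) times the
true range. Δt = 0.002 and ζ = 1 keep the Euler–Maruyama equilibrium
bias negligible against the stiffest fixture wells (Δt·U″/2ζ ≈ 0.03).

Forces are read by bilinear interpolation from an internal 256×128
table to which each hill is added once, keeping the step cost flat in
the hill count; the emitted HILLS records themselves are exact. With a
0.035-rad grid spacing the interpolation error is far below kT and does
not measurably perturb the sampled distribution (the Boltzmann-marginal
and equipartition tests pass against analytic references).

**Double-well fixture.** Two Gaussian wells (σ = 0.55 rad) at an
E₅-like point (φ = 300°, θ = 54.74°) and a ¹S₃-like point (φ = 210°,
θ = 125.26°), 1.997 rad apart; the equal-depth value 8.087 kcal/mol is
fixed by the closed form so the lowest pass sits exactly 5.0 kcal/mol
above the bottoms (a detour through the flat far field would cost the
full depth). An `asymmetry` parameter deepens the southern well:
−2 kcal/mol gives a wild-type-like landscape (reactive north favored,
ΔG_r/nr < 0), +2 a dormant-mutant-like one (ΔG_r/nr > 0, higher escape
barrier from the occupied basin). With the default protocol the 5.0
kcal/mol barrier is recovered from the emitted hills within 0.5 kcal/mol
(documented seed 12345; ~14–20k hills, a few seconds of sampling).

**What the generator does and does not emulate.** It reproduces the
statistical structure the analysis layer consumes: well-tempered height
decay, periodic/bounded CV topology, basin asymmetry, and known analytic
free energies. It does not emulate atomistic force fields, inertial or
multi-timescale dynamics, CV hysteresis from orthogonal slow modes, or
the electronic-structure energetics of bond breaking — so passing tests
validate the *analysis*, not any claim about a specific enzyme. Ring
fixtures are ideal hexagons plus prescribed out-of-plane displacements
and optional Gaussian noise; toy SASA complexes are single-atom ligands
in Fibonacci-lattice shells with a spherical-cap mouth, giving closed
form exposure bounds.

## Numerical choices and edge cases

- Degenerate (planar) puckers are flagged, not raised; classification
  and reactivity refuse them explicitly.
- Conformer classification ties (exactly equidistant references) break
  by fixed table order; MFEP ties break by accumulated energy, then node
  count, making every reported path deterministic.
- Periodic axes exclude the duplicate endpoint node; bounded axes
  include both endpoints. Node area elements are uniform.
- Hills with γ ≤ 1 under the tempered dialect, empty partition regions,
  empty region masks, non-positive bin widths and zero-length angle
  vectors raise immediately with descriptive messages.
- The equator boundary, the 300 K temperature of the Boltzmann
  aggregation, and the tempered height dialect are all explicit,
  logged choices — each is the common convention but none is universal,
  and each is overridable where deposited data disagree.

## Problem sizes

The test suite and `scripts/acceptance.py` size their computations for
interactive turnaround: 144×72 (or 72×36) reconstruction grids, 10⁵–10⁶
sampler steps depending on the check, 50-hill oracle comparisons, 100
random minimax grids up to 6×6, and 10⁶-point SASA oracles. These sizes
were chosen so each check's statistical or discretization error is well
inside the tolerance it asserts.
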