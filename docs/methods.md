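# Methods

This note documents the model implemented by `laminachain`, the
conventions and numerical choices behind it, and what the test suite
does and does not establish.

## Model and assumptions

The chromatin segment is a chain of N = 12 hard beads of radius
r_bead = 15 nm. At a linear mass density of 120–150 bp/nm this maps to
roughly 50 kb — a sub-LAD scale segment. The material contour length is
L_C = 2·r_bead·N = 360 nm (the center-to-center span of the taut chain,
330 nm, plus one bead radius at each end). The nucleus is a sphere of
radius r_nucleus = 5 µm centered at the origin; the model requires
r_nucleus ≥ 10·L_C so the periphery is locally almost flat on the scale
of the chain. "Height above NP" of a point r is r_nucleus − |r|,
negative outside the sphere.

Energies are expressed in k_BT (k_BT ≡ 1, no temperature parameter) and
lengths in nm. The Hamiltonian contains:

* **Bending** — discrete worm-like chain, `(L_P/2r_bead)·Σ(1−cos θ)`.
  The persistence length L_P is the single stiffness dial; the study
  grid is {5, 50, 100, 200} nm, spanning flexible euchromatin-like to
  near-rigid heterochromatin-like fibers. Torsion is omitted.
* **Stretching** — harmonic bonds `(L_P/r_bead³)·Σ(b−2r_bead)²` with
  equilibrium length one bead diameter. Note the stiffness scales with
  L_P: flexible chains also have soft bonds (thermal bond s.d. ≈ 18 nm
  at L_P = 5 nm, ≈ 5.8 nm at L_P = 50 nm). Sampling-time sanity checks
  use a connectivity band of 2·r_bead + 8 bond s.d. for this reason.
* **Excluded volume** — standard WCA between nonconsecutive beads:
  `4ε[(σ/r)¹² − (σ/r)⁶] + ε` for r ≤ 2^{1/6}σ, zero beyond, with
  ε = 1 k_BT and σ = 2r_bead/2^{1/6}. This is the unique purely
  repulsive, continuous truncated-shifted Lennard-Jones with its cutoff
  at the bead diameter.
* **Wall spring** — beads escaping the nucleus feel
  `(k/2)(|r|−r_nucleus)²` with k = k_BT/r_bead², acting on bead
  centers. Excursions are penalized, not forbidden; a neutral-surface
  chain can graze slightly beyond the periphery.
* **Surface attraction** (enabled when ε_ads > 0) — a 10–4 potential
  from integrating 12–6 Lennard-Jones pair interactions over the
  nuclear sphere of radius R = r_nucleus:

      U(r) = 4π·ε_ads·(R/r)·[ (1/5)((σ/(R−r))¹⁰ − (σ/(R+r))¹⁰)
                              − (1/2)((σ/(R−r))⁴  − (σ/(R+r))⁴) ]

  with σ = r_bead and ε_ads the pair well depth in k_BT. The potential
  diverges at the periphery, has its minimum at a height ≈ r_bead
  (15.0011 nm — exactly the imposed anchor height) with depth
  ≈ 4π·0.3·ε_ads ≈ 3.78·ε_ads k_BT, and is negligible (<10⁻⁶ k_BT) deep
  in the interior. Three conventions deserve emphasis, because the
  10–4 family admits several parameterizations:

  1. ε_ads scales the *whole* potential, so the adsorbed-state energy
     gain is of order N·ε_ads·k_BT — the scaling under which the
     entropy-vs-energy argument for the adsorption threshold
     (ε_ads ≳ 1/N for a stiff pinned chain) holds.
  2. The attractive sphere has radius R = r_nucleus, not
     r_nucleus − r_bead. This places the hard divergence at the
     periphery itself, the well minimum at the anchor height, and the
     attraction range (≈ one bead radius) inside the ≤ 30 nm adsorption
     zone. The alternative (R = r_nucleus − r_bead) would put the well
     minimum exactly on the 30 nm classification threshold — a strongly
     adsorbed bead would then be classified desorbed half the time —
     and would assign infinite energy to the standard initialization at
     height 15 nm, so it is not viable.
  3. Neutral-surface simulations (ε_ads = 0) carry no surface term at
     all: the periphery interacts with the chain only through the wall
     spring. A consequence worth knowing is that the neutral surface is
     *not* the ε_ads → 0 limit of the attractive one: any ε_ads > 0
     erects a repulsive core that excludes bead centers from roughly
     the lowest 10 nm above the periphery, which a neutral chain can
     visit. F(ε_ads) is therefore monotone on ε_ads > 0 but can drop
     between ε_ads = 0 and very weak attraction. Carrying the repulsive
     core into the neutral case instead would shift the neutral
     configuration census by ~10 percentage points, away from the
     reference behavior this package reproduces.

## Anchoring and the pinning protocol

Anchor sites live on the sphere of radius r_nucleus − h, h = r_bead.
Bead 1 is pinned from the start. The chain initializes as a geodesic
arc at constant height h with all bonds at 2·r_bead (bending cost of the
curvature ≈ 3·10⁻⁴ k_BT). With two anchors the arc heads toward the
second site, whose Euclidean (chord) separation from the first is d_E;
d_E > L_C is rejected as unreachable. Bead 12 starts free and is driven
onto its site by Metropolis dynamics under the full Hamiltonian plus a
harmonic tether `(L_P/r_bead³)·|r₁₂ − a₂|²` (the stretching form with
zero rest length). When bead 12 comes within R_move of the site —
checked once per sweep — it is snapped exactly onto it, frozen, and the
tether removed. Pinning sweeps count against the pre-equilibration
budget; failure to capture within that budget aborts with a diagnostic.

## Monte Carlo scheme

One MCStep: pick a free bead uniformly, displace it by a vector drawn
uniformly from the ball of radius R_move = r_bead/5 = 3 nm (rejection
sampling from the bounding cube), accept with min(1, e^(−ΔU)). One
MCSweep = n_free steps. ΔU is evaluated incrementally — only the bond,
bending, pair, wall, surface and tether terms touching the moved bead —
in a numba-compiled kernel; agreement with full recomputation is
enforced to 10⁻⁹ k_BT by the tests. Proposals with a bead at or beyond
the attractive sphere get ΔU = +∞ and are rejected.

Randomness: one `numpy` Generator per replicate, seeded
base_seed + replicate_id; the random streams (bead picks, displacements,
acceptance uniforms) are drawn at the driver level and passed to the
kernel, so a (seed, params) pair fully determines the trajectory
bit-for-bit.

Physical time is metadata only: dt per sweep = dr²/D = 0.09 s with
D = 10⁻⁴ µm²/s, a chromatin diffusion constant near the periphery.
Dynamics are unaffected by this mapping.

### Schedules

The default desk-scale schedule is 10⁷ sweeps per replicate with 10⁵
discarded as pre-equilibration, one sample every 10³ sweeps, and 3
replicates (≈30 s/replicate on one CPU). The publication-scale schedule
(5·10⁸ sweeps, 5·10⁶ pre-equilibration) is available as
`PAPER_SCHEDULE` and is configuration-reachable but takes hours per
condition. Reported statistics are means over replicates with s.e.m.
computed across replicate means — not across raw samples, whose
autocorrelation would bias a naive s.e.m.

## Configuration analysis

A bead is **adsorbed** when its center-to-NP height is ≤ r_bead + 15 nm
= 30 nm (inclusive). Maximal adsorbed runs are trains (a single
adsorbed bead is a size-1 train; anchored beads count toward train
sizes); maximal desorbed runs containing a chain end are tails (one-
anchor chains have at most one, two-anchor chains none); interior
desorbed runs are loops. Censuses report the joint
(tails, trains, loops) histogram over sampled structures, segment-size
distributions, and per-bead state frequencies.

The regime statistic is F = f_train − f_other in percent, computed over
*free-bead* observations only (anchored beads are trivially adsorbed);
f_other = f_loop + f_tail with one anchor and f_loop with two. Regime
thresholds: adsorption F > 50, adsorption–desorption 0 < F ≤ 50,
desorption F ≤ 0, applied to the pooled replicate-mean F.

## Rigid-rod reference

For L_P ≫ L_C a one-anchor chain at a neutral surface approaches a
straight rod hinged at the anchor. The reference is computed by Monte
Carlo: rod orientations drawn uniformly over the solid angle, rejecting
any orientation that places a bead center below the periphery (the
hard-constraint reading of the wall spring), averaging bead heights over
accepted draws. An equilibrated L_P = 200 nm simulation tracks this
reference within 20% per bead (the free end sags, as L_P is only about
half a contour length); reaching that agreement requires ≳10⁶
pre-equilibration sweeps because the chain starts lying along the
surface, far from the rod-like ensemble.

## What the synthetic fixtures are and are not

The fixture generator emits small trajectories with exactly known
segmentations (straight chain, all-adsorbed, 2-train/1-loop, random
heights) by placing beads along a great-circle fan at prescribed
heights. They exercise the classifier, serialization and CLI paths with
ground truth; they are not samples of the physical model, and passing
them says nothing about Boltzmann fidelity — that is established
separately by the analytic checks (joint-angle Langevin average, dimer
bond-length distribution against quadrature, Metropolis acceptance
rate) on the simulator itself.

## Problem sizes used in the checks

Analytic and structural checks run in milliseconds. Stochastic checks
use 3 replicates × 10⁷ sweeps for the two neutral-surface census
conditions (the package's standard desk protocol), 3 × 10⁶ sweeps for
the strong-adsorption regime call, 3 × 10⁶-sweep cells for the reduced
qualitative phase grid (one anchor, L_P ∈ {5, 50},
ε_ads ∈ {0, 0.05, 1}), and 3 × 10⁶-sweep points for the F-vs-ε_ads
monotonicity scan. These sizes give census percentages stable to a few
percentage points across seeds.

## Known limitations

* The 12-bead chain models a sub-LAD segment; conclusions about whole
  LADs (100 kb–Mb) require longer chains, which are config-reachable
  (`n_beads`) but not validated here.
* No torsional stiffness, no hydrodynamics, no bead–bead attraction:
  regimes arise purely from surface attraction vs. configurational
  entropy.
* The neutral periphery is soft (spring on centers): bead centers can
  approach and slightly cross the surface. See the surface-potential
  discussion above for why this is kept.
* With the implemented 10–4 potential, the adsorption–desorption
  transition for a one-anchor semi-flexible chain sits between
  ε_ads = 0.1 and 1 (measured F: −77 at 0.1, +90 at 1); intermediate
  attractions in the 0.005–0.1 range all classify as desorption for
  flexible chains. Regime *ordering* in ε_ads is robust; the absolute
  ε_ads value at which the transition occurs depends on the exact
  prefactor conventions of the surface potential and should not be
  over-interpreted.
* Physical time is a fixed affine mapping of sweep count; kinetic
  quantities (dwell times) are meaningful relatively, not absolutely.
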