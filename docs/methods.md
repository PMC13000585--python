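# Methods

## Candidate library

A candidate is an aromatic six-ring with an oxygen radical at position
1 and one of {H, Me, OMe, tBu, COOH} at each of positions 2–6. Two
assignments describe the same molecule when related by the ring mirror
(2↔6, 3↔5), so patterns are stored canonically: the lexicographically
smaller of a tuple and its reverse under the fixed code order
H < Me < OMe < tBu < COOH. The order is arbitrary but load-bearing for
reproducibility — it decides which mirror representative is stored and
therefore the candidate ids and the per-position counts. Counting
orbits of the mirror involution gives (5⁵ + 5³)/2 = 1625; the 5³ term
is the palindromes the mirror fixes.

Filters: (1) at most two tBu and at most two COOH, counted
independently; (2) no ring-bonded adjacent pair — (2,3), (3,4), (4,5),
(5,6) — may be tBu/tBu or tBu/COOH; positions 2 and 6 both bond to C1
and are deliberately *not* treated as adjacent, which is why rule
(3) separately excludes one tBu plus one COOH on the ortho pair; (4) at
most four non-H substituents. Filters are mirror-invariant, so
filtering and canonical deduplication commute (verified exhaustively
over all 3125 raw tuples); the survivor count is 718.

Masses use IUPAC standard atomic weights at four significant figures
(shipped as `data/atomic_masses.csv`); SMILES are built positionally
and canonicalized with RDKit, and `smiles_to_pattern` inverts them by
locating the radical oxygen and walking the ring. Per-position
substituent counts are reported over canonical orientations only, which
skews them toward low-order codes at position 2 — a reporting
convention, stated in the table metadata, not a chemical claim.

## Synthetic data and what it does (not) emulate

The generators replace reactive MD with controlled stand-ins:

* **Brownian trajectories** — i.i.d. Gaussian steps with per-component
  variance 2·D·Δt, emitted unwrapped (MSD needs unwrapped coordinates).
  Planted D defaults span 0.01–0.1 Å²/ps, the order of magnitude of
  small-molecule diffusivities in light oils (~10⁻⁶–10⁻⁵ cm²/s).
* **Reaction series** — each of 100 radicals draws an exponential
  reaction time at rate k, so E[N(t)] = 100(1 − e^(−kt)): the exact
  stochastic counterpart of the curve the kinetics stage fits, including
  the finite-pool saturation.
* **H-bond scenes** — a donor O–H pair placed in the bonded geometry in
  a Bernoulli(occupancy) subset of frames and >4 Å away otherwise, with
  the donor–H–acceptor angle constructed exactly at the hydrogen.
* **Mixtures** — rigid copies of idealized geometries packed by
  rejection sampling (uniform random positions/orientations, minimum
  intermolecular distance 2 Å, minimum image). The hydroperoxide is a
  tert-butyl hydroperoxide proxy: downstream stages consume only the
  labeled O–H pair, and the small rigid body keeps packing fast.
* **Transfer trajectories** — piecewise-static frames in which, at each
  radical's drawn reaction time, the nearest free hydroperoxide H is
  teleported to 0.5 Å from that radical's oxygen. Deliberately
  non-physical: the contract is only that the 0.9 Å criterion fires at
  the planted times, which lets the event detector be tested end to end.

Passing tests therefore demonstrate that each analysis recovers what it
is defined to measure — not that real PAO systems have these
diffusivities, occupancies, or rates. Nothing here models force fields,
thermostats, density relaxation, solvent caging, or correlated motion.

## Idealized geometries

Planar hexagonal ring (C–C 1.39 Å), in-plane C–O• of 1.25 Å,
substituents grown from internal-coordinate templates with standard
bond lengths. Substituent local frames are defined mirror-covariantly
(the in-plane tangent flips handedness between positions 2,3 and 6,5),
so palindromic patterns give exactly mirror-symmetric structures;
position 4, its own mirror image, is restricted to self-symmetric
orientations. Crowded ortho/meta neighbors are handled by fixed
out-of-plane tilts alternating up (positions 2, 4, 6) and down (3, 5)
plus tuned torsional azimuths; OMe bends its methyl out of the ring
plane and COOH stands perpendicular to it. These orientations stand in
for the angle strain and correlated rotations a real crowded molecule
relaxes into, and were chosen once so that no nonbonded pair in any of
the 718 geometries comes closer than 1.6 Å. Consequences: buried-volume
values are molecule-only and conformer-specific — comparable across
candidates, not absolute.

## Descriptors

* **MSD/diffusion** — sliding-origin average over all frame-grid lags;
  the Einstein fit uses ordinary least squares over lags in the 10–50%
  window of the maximum lag (origin statistics degrade at long lags,
  and the window avoids anchoring on the trivial zero at lag 0);
  D = slope/6 for 3-D diffusion (dimensionality configurable).
* **H-bonds** — strict cutoffs (< 3 Å donor–acceptor, > 150°
  donor–H–acceptor); donor oxygens are role-tagged (hydroperoxide and
  carboxyl hydroxyls) and their hydrogens located by covalent proximity
  (< 1.25 Å, same molecule). Protection probability is the per-radical
  fraction of frames with ≥1 accepted bond, averaged over radicals and,
  at pipeline level, over realizations. All O–H groups count as donors.
* **Buried volume** — percent of a 3.5 Å probe sphere centered on the
  phenoxyl oxygen covered by the vdW spheres (Bondi radii, shipped as
  `data/vdw_radii.csv`) of all other atoms, hydrogens included, the
  center atom excluded (otherwise every value carries a constant
  floor). Grid integration at 0.1 Å resolution by default; the
  Monte-Carlo route exists as an independent estimate and both are
  validated against the analytic two-sphere lens formula.
* **Steric maps** — molecule rotated so the ipso-C→O axis is vertical;
  the map records the top vdW surface height over the perpendicular
  grid, clipped to the probe sphere.
* **Event detection** — first frame at which an unreacted (O, H) pair
  is strictly within 0.9 Å (minimum image); events are irreversible and
  one-per-atom, with greedy nearest-pair matching if several pairs
  qualify in the same frame.

## Kinetics

N(t) = N∞(1 − e^(−kt)) is fitted by nonlinear least squares
(scipy, trust-region with bounds N∞ ≥ 0, k ≥ 0), initialized at
N∞ = max counts and k = ln2/t_half. N∞ stays free rather than pinned to
the radical count: the curve is a numerical summary of saturation, not
a mechanism. Realizations are averaged *before* fitting. Unweighted
least squares; time in ns so k lands in ns⁻¹. Degenerate series
(all-zero, or saturated before the first frame) are flagged
non-converged, never raised, so a screen over many candidates cannot be
aborted by one bad series.

## Regression

Features are z-scored with the population (1/n) standard deviation —
the convention only rescales coefficients — and the model is OLS with
intercept, so β₀ equals the mean rate constant. R² with TSS = 0 is
defined as 0 with a warning. Prediction on new candidates requires the
training moments, which the model object carries; ranking is ascending
in predicted k with id tie-breaks. No inference machinery is attached:
standard errors appear only inside recovery tests.

## Pipeline and planted-truth link

The screening pipeline plants per-candidate truth: D uniform in the
documented range; H-bond occupancy bimodal — high (0.55–0.90) for
COOH-bearing candidates, low (0.05–0.35) otherwise, mirroring the
donor-driven separation of protection probabilities; V_bur fixed by the
geometry. The planted rate constant is, by default, affine in the
standardized planted features with weights (+1.4, −2.0, −1.1) around an
intercept of 7.5 ns⁻¹ and Gaussian noise of SD 1.96 (signal-to-total
variance ≈ 0.65), so the regression stage has a recoverable signed
signal; an explicit evenly spaced k-span is available for pure
rate-recovery experiments. Stages exchange small tables via the run
directory and regenerate trajectories deterministically from
(seed, config) instead of serializing them; the CLI subcommands
therefore compose to byte-identical outputs with `run-all`.

Problem sizes in the analysis scripts (24-candidate screen, 50-seed
rate recovery, 10⁵ Monte-Carlo points) are desk-scale choices that keep
a full reproduction in the minutes range while leaving every estimate
well inside its validated tolerance.

## Known limitations

* Descriptors from static idealized geometries omit the dynamic
  environment contribution to buried volume; reported percentages are
  systematically lower than trajectory-averaged values over packed
  systems would be, and only their ordering is meaningful.
* The planted-truth link between descriptors and rates is linear by
  construction; the pipeline cannot discover nonlinearity that the
  generator does not produce.
* Event detection at frame resolution quantizes reaction times to 4 ps;
  at rates far above ~100 ns⁻¹ the first frame saturates and k becomes
  unidentifiable (flagged, not estimated).
* The substituent alphabet is configurable but untested beyond the five
  codes; the geometry templates cover exactly those five.
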