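# Methods

This note records the models implemented in `icebind`, the defaults and
their rationale, the numerical choices, and what the synthetic test systems
do and do not establish about real simulation data.

## Phase classification

Water is represented by oxygen positions only: the bond-orientational
classification and every downstream metric operate on molecular (oxygen)
neighbour geometry, so hydrogens and proton disorder are irrelevant to the
labels. Each molecule's four nearest neighbours (orthorhombic minimum
image) define q3m(i) = Σ_j Y3m(r̂_ij), m = −3…3. The bond correlation
c(i,j) is the normalized real inner product of the two q3 vectors; it is a
rotation-invariant scalar contraction, which the tests verify to 1e−9.

Bond classes and the label table (staggered c ≤ −0.8; eclipsed
−0.35 ≤ c ≤ 0.25; cubic = 4 staggered; hexagonal = 3 staggered +
1 eclipsed; interfacial = exactly 2 staggered, or 3 staggered with no
eclipsed bond; otherwise liquid) follow the established CHILL+ scheme;
clathrate patterns are not assigned because no clathrate-forming systems
appear here.

Two single-pass corrections then sharpen the ice front, in this order:

1. ice-labelled molecules with fewer than 3 other ice-labelled molecules
   within 0.5 nm become liquid ("fewer than three" is a strict count; the
   pass is simultaneous — it evaluates the input labels, so a mutually
   supporting sparse pair drops together);
2. liquid molecules within 0.35 nm of hexagonal or cubic ice (interfacial
   ice does not recruit) are absorbed into the ice phase. Absorption does
   not chain: newly absorbed molecules recruit no one. The absorbed
   molecules keep a distinct label so the per-frame table can report them
   separately; they count as ice in every total.

Distance comparisons at thresholds are strict (<). Neighbour ties (exactly
equal 4th-neighbour distances, common on ideal-lattice surfaces where the
second shell is 6-fold degenerate) are resolved by (distance rounded to
1e−12 nm, particle index) after querying a candidate set wide enough to
contain the whole tied shell; this makes labels deterministic and
independent of KD-tree internals.

## Ice-binding metrics

* **Attachment**: a −CH2 carbon is attached when ≥ 6 ice-phase molecules
  (the hexatomic ring of a basal face — the first solvation shell) lie
  within 0.55 nm. Corrected labels are used; interfacial and absorbed ice
  count as ice.
* **Surface height** z_ice: mean z over ice molecules within 0.3 nm of the
  frame's maximum ice z (about one bilayer), ignoring ice below a
  configurable z-floor so a restrained bottom slab face cannot leak in. The
  0.3 nm window and the layer-mean are this package's definition — "the
  position of the ice surface" admits several; the window is exposed as a
  parameter, and a per-lateral-cell maximum variant is available for rough
  fronts.
* **Embedded depth**: minimum chain z minus z_ice; negative values mean the
  chain dips into the surface.
* **State**: engulfed when ≥ 90 % of heavy atoms lie below z_ice (the
  threshold is configurable; "overgrown" has no unique geometric
  definition), bound when at least one −CH2 is attached and the chain is
  not engulfed, otherwise unbound.
* **Coverage area**: heavy atoms of bound chains are projected onto the
  lateral plane and rasterized as disks of radius 0.5 nm on a periodic grid
  (default spacing 0.02 nm, giving ≤ 2 % quantization error on a single
  disk; the error is second-order in spacing/radius). Only chains currently
  bound contribute. The 3.3 nm² engulfment-resistance value is carried as a
  reporting threshold in the run configuration, not as logic.
* **Hydrogen bonds**: donor–acceptor < 0.35 nm and H–donor–acceptor angle
  < 30°, one bond per donor–acceptor pair, partitioned by acceptor phase
  when labels are supplied. Proline backbones carry no amide hydrogen, so
  generated chains have empty donor lists; donors matter for water→polymer
  bonds and explicit-water fixtures.

## Conformation metrics

Torsions use the standard signed atan2 convention, range (−180, 180].
PPII content is the fraction of evaluable residues with φ ∈ [−110, −30]
and ψ ∈ [120, 180] (closed intervals, as the bracket notation implies);
terminal residues lacking a full (φ, ψ) pair are excluded from the
denominator, and multi-frame summaries pool residue-frames. R_g is
mass-weighted about the weighted centroid. The conformer population ratio
is p(L)/p(C) = exp(ΔG_CL / k_B T) with ΔG_CL = G_C − G_L and
k_B = 0.0083145 kJ/mol/K; energies are kJ/mol throughout.

## Toy metadynamics

The engine runs overdamped Langevin dynamics *on the collective variable
itself*: ds = βD F dt + √(2D dt) ξ, with the CV moving over an analytic
potential. Rationale: the estimator properties under test — well-tempered
height damping, bias-to-free-energy inversion, Tiwary–Parrinello
reweighting, replicate uncertainty — are properties of the bias machinery,
not of molecular dynamics, and every one of them has a closed-form
reference on an analytic landscape. Defaults: dt = 0.005 ps and
D = 0.05 CV²/ps, chosen so the per-step displacement (~0.02) stays well
below the Gaussian width σ = 0.1 and drift stays small against the
steepest toy-potential gradients.

Deposits every `stride` steps add a Gaussian of height
W·exp(−V(s)/k_B ΔT), ΔT = (γ−1)T. The bias and its gradient are
accumulated on a grid and linearly interpolated (engine-style); kernel
bookkeeping (centre, height, step) is kept for reweighting. Reweighting
computes c(t) at each deposit by quadrature of
(1/β) ln [∫ e^{βγV/(γ−1)} / ∫ e^{βV/(γ−1)}] on an internal grid that
spans everything sampled — the normalization must see the whole biased
region, not just the reporting window — and weights each sample by
exp(β(V(s_t, t) − c(t))) with the bias frozen at the most recent deposit.
The first 20 % of samples are discarded as transient. The requested output
grid is a reporting window: samples outside it are excluded from the
histogram (an error is raised only if the window misses most of the
sampling); unvisited bins are NaN and replicate averaging masks any bin
not visited by every replica.

The benchmark landscape is the symmetric quartic double well
U(s) = h((s/a)² − 1)², h = 10 kJ/mol (4 k_BT at 300 K), minima at ±1.
The uncertainty benchmark runs three replicas (W = 1 kJ/mol, σ = 0.1,
γ = 20, stride 500, 4·10⁶ steps — sizes chosen so the statistic is stable
across seeds) and reports the maximum per-bin standard error over the grid
s ∈ [−1.6, 1.6] (spacing 0.05). That window covers both basins and the
barrier up to ~8 k_BT above the minima — the landscape one would plot;
bins far up the confining walls (|s| ≈ 2 sits ~35 k_BT up) are visited
only by a handful of excursions and their estimates are not meaningful at
this run length. The separate bias-inversion convergence check uses a
gentler schedule (W = 0.2, γ = 10, 4·10⁶ steps) because the instantaneous
−γ/(γ−1)·V estimate carries ripple on the scale of W; the reweighting
estimator, which is the one actually used for profiles, is tested at full
W.

## Synthetic systems: what they emulate, and what they do not

* **Lattices.** Ideal oxygen sublattices: cubic ice is the 8-molecule
  diamond-cubic cell (a = 4d/√3); hexagonal ice is the 8-molecule
  orthohexagonal lonsdaleite cell (a = d√(8/3), b = a√3, c = 8d/3, two hcp
  sublattices offset by 3c/8). The crystallographic hexagonal cell holds 4
  molecules but cannot tile an orthorhombic box, so cell counts here are
  multiples of 8. Default d = 0.276 nm. Both lattices are bipartite
  4-regular under periodic boundaries, which the tests verify by brute
  force.
* **Liquid** is random sequential insertion with a minimum distance
  (default 0.26 nm) — excluded volume only, no orientational or
  tetrahedral structure. That is deliberate: liquid must classify as
  liquid, and a structureless liquid is the cleanest negative control. It
  does *not* reproduce the first-shell coordination of real water, so the
  absorption rule at a real disordered interface is exercised only through
  constructed fixtures, not through the generator's liquid.
* **Chains** are built from internal coordinates (φ = −75, ψ = 145,
  ω = 180 for the PPII form; the analysis itself fixes only the
  classification window, not these ideal values). Coils add seeded
  Gaussian torsion noise and random cis-ω flips. Proline rings are three
  pseudo-carbons placed by fixed internal coordinates — they exist to be
  −CH2 attachment probes, not to model ring puckering.
* **Advancing fronts** freeze lattice sites below a rising front height
  (site positions plus fresh per-frame jitter) and redraw everything above
  as excluded-volume liquid, conserving molecule identity and count. The
  liquid is kept 0.48 nm clear of ice sites — just beyond the second
  lattice shell (1.633·d ≈ 0.45 nm) — so that at zero jitter the surface
  bond patterns, and hence the labels, are deterministic.

  A free slab's outermost one-to-two sublayers have incomplete neighbour
  shells, and no neighbour-geometry classifier can label them ice from the
  ice side alone; classified totals therefore track the site-count truth
  with a surface deficit of that order. The generator consequently emits
  two truths per frame: all ice sites, and the *core* (sites whose four
  lattice bonds all connect to present ice). The guarantees the tests pin
  down at zero jitter are sharp: every core molecule is labelled ice, no
  true liquid is ever labelled ice, counts are monotone under growth and
  constant at zero velocity, and the classifier's surface height lands
  within 0.15 nm (half a bilayer) of the core-ice top. Passing these says
  the pipeline is exact away from interfaces and conservative at them; it
  does not calibrate the residual surface bias against real liquid-water
  interfaces.

## Defaults ledger

All thresholds live in `RunConfig` (YAML-serializable): sparse-ice radius
0.5 nm / 3 neighbours; absorption 0.35 nm; attachment 0.55 nm / 6 ice;
H-bond 0.35 nm / 30°; coverage radius 0.5 nm, grid 0.02 nm; surface layer
0.3 nm; engulfment fraction 0.9; PPII windows [−110, −30] × [120, 180];
coverage-resistance report threshold 3.3 nm². Internal units are nm,
kJ/mol, ps; file formats are PDB/GRO (via MDAnalysis, Å converted at the
boundary) and extended XYZ with `Lattice=` box metadata; triclinic boxes
are rejected, and every stochastic routine takes an explicit seed.

## Known limitations

* No clathrate categories, no hydrogen-based ice criteria, no
  density-profile interface locators.
* The toy metadynamics is one-dimensional overdamped dynamics on the CV;
  no molecular system, no multiple walkers, no transition-time estimates.
* Coverage projection assumes the surface normal is z and the box
  orthorhombic.
* The synthetic liquid's lack of hydrogen-bond network structure means
  interfacial-water absorption statistics on generated fronts are lower
  than they would be at a real ice/water interface.
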