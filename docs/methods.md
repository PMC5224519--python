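# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would otherwise have to reverse-
engineer.

## Structures and trajectories

All geometry runs on a single container: a `Trajectory` of `StructureModel`
frames read from fixed-column PDB, one frame per `MODEL` block (one implicit
frame when absent). `ATOM` and `HETATM` records are both kept — glycan
residues (NAG/BMA/MAN) are deposited as heteroatoms and must be first-class.
Residue numbers are the author numbering exactly as printed, because
receptor residues are cited by crystal-structure numbers. Alternate
locations resolve to the highest-occupancy conformer, ties to the first
listed; this makes parsing deterministic. Coordinates are written to three
decimals (0.001 Å), which bounds the read→write→read round-trip error;
anything requiring better precision should stay in memory. Binary
trajectory formats (DCD/XTC) and mmCIF are deliberately out of scope: the
analyses here consume modest numbers of frames and multi-model PDB keeps
the I/O dependency-free and text-only. Frame striding and analysis windows
(e.g. discarding an equilibration prefix) are exposed as a `frame_window`
parameter rather than guessed.

## Hinge angle

The relative disposition of the two extracellular domains of an Fcγ-type
receptor is summarised by one scalar: the angle at a vertex residue between
vectors to an outer residue of each domain. The anchor atoms are Cα by
default — the convention for backbone-level interdomain geometry — and
overridable per anchor. The measure is invariant under rigid motion and
symmetric in the two outer anchors; both properties are tested, the first
to 1e-6 degrees over random rotations and translations. Degenerate
(coincident-anchor) input raises rather than returning NaN. For orientation:
the high-affinity receptor FcγRI (measured on its crystal structure with
anchors Ile96/Gly103/Ser110) sits near 35°, while low-affinity receptors
sit in the 50–55° range; the toolkit ships no default anchors for receptors
whose triplet construction it cannot verify.

## Contact counting

Contacts between two atom selections use heavy atoms only, at an inclusive
cutoff (d ≤ cutoff) of 3.0 Å by default — roughly a hydrogen-bond
donor–acceptor distance, conventionally quoted between heavy atoms even in
simulations that carry explicit hydrogens. Two counting units are
supported: distinct contacting residues of the second selection (the unit
the glycan classifier needs) and qualifying atom pairs (symmetric under
selection swap). A k-d tree accelerates the neighbour search; the test
suite holds it equal to the exhaustive O(N²) count on 100 random dense
frames, so the acceleration is an implementation detail that cannot change
results. No periodic-boundary imaging is attempted — frames are assumed
whole — but a warning is emitted when selections sit implausibly far apart
(> 500 Å), the signature of an un-imaged box.

## Glycan two-state classification

The Fc N-glycan is modelled as a 7-residue topology: chitobiose-core
GlcNAcs (indices 1–2), β-mannose (3), α1–3 branch mannose (4), α1–6 branch
mannose (5) and the two terminal mannoses of the α1–6 arm (6–7). A frame
is classified by counting Cγ2-domain residues with any heavy atom within
the cutoff of glycan residues 2–6; at most `loose_threshold` (default 2)
such residues means the chain is in the loosely-associated configuration,
otherwise tightly bound. Both the probe index set and the threshold are
parameters: the residue-window convention (whether "2–6" starts at the
second core GlcNAc or at the β-mannose) is a figure-numbering ambiguity in
the source literature, so the mapping is explicit and configurable rather
than hard-coded. The reference selection defaults to the Cγ2 domain of the
glycan-bearing heavy chain only; cross-chain contacts are excluded because
the association being classified is to the chain's own Cγ2, but the
selection is caller-supplied and can be widened. Classification inherits
rigid-motion invariance from the contact counter. State fractions are
simple frame proportions; on concatenated trajectories they equal the
frame-weighted average of the parts (tested to 1e-12).

Published trajectory fractions for this system (one chain ~97% bound, the
other loose ~35% of frames) come from ≳120 ns atomistic MD and are not
reproducible at desk scale; the classifier is instead validated by exact
agreement with designed ground truth and by binomial recovery of sampled
fractions (within three standard errors at 2 000 frames).

## Lectin accessibility

The accessibility test idealises the question "can a carbohydrate-
recognition domain reach this mannose?" as constrained sphere placement.
The cavity entrance is an ellipse (default semi-axes 1.75 × 1.0 nm, i.e. a
3.5 × 2 nm opening) in a user-supplied plane — the toolkit does not try to
detect the cavity from coordinates, because the opening is a published
dimension, not an algorithmically defined surface. The probe (default
radius 1.5 nm, a 3 nm CRD sphere) may occupy any centre at least one radius
outside the plane, or anywhere in the elliptical channel through the
entrance shrunk by the probe radius along each semi-axis (the conservative
condition for the sphere to pass without clipping the rim; a probe wider
than the opening is reported as blocked, not an error). The clearance is
the minimal probe-surface-to-target distance over that reachable set —
computed exactly: a half-space distance and a 2-D point-to-ellipse distance
solved by safeguarded bisection — and the target is accessible when the
clearance is within the contact distance (3 Å default, boundary inclusive
with a 1e-9 nm guard against floating-point rounding of the unit
conversion). Cavity walls other than the entrance plane are not modelled;
the test answers entrance-limited accessibility only.

## SPR kinetics

Sensorgrams follow the 1:1 Langmuir model. The closed-form association
response R(t) = R_eq·(1 − e^(−(k_on·C + k_off)·t)) with
R_eq = R_max·C/(C + K_D), and exponential dissociation after the buffer
switch, are used for both simulation and fitting; the analytic solution is
held to 0.1% of independent ODE integration in the tests. Fitting is
global — one (k_on, k_off, R_max) shared across all concentrations of a
series, the standard treatment of multi-channel data over one surface —
by derivative-based least squares with the rate parameters log-transformed
to enforce positivity (tolerances 1e-12, at most 10 000 evaluations).
Initial guesses are derived from the data: the response plateau seeds
R_max, the log-linear dissociation slope seeds k_off. K_D is reported as
k_off/k_on, never fitted independently. Non-convergence is flagged on the
result, not raised. Mass-transport limitation, bulk refractive-index
jumps, drift, and multivalent-analyte models are intentionally absent:
avidity effects of oligomeric analytes surface only through the apparent
rate constants, which is exactly what a 1:1 fit of such data reports.
Simulation noise is i.i.d. Gaussian in RU.

One caution for users of published rate triplets: printed (K_D, k_on,
k_off) sets are not always mutually consistent. An example encountered
while validating this module reports K_D = 3.91 nM alongside
k_on = 2.77 × 10⁴ M⁻¹s⁻¹ and k_off = 9.46 × 10⁻⁵ s⁻¹, whose ratio is
3.42 nM; `kd_from_rates` always reports the ratio.

The default simulation conditions (k_on = 6.68 × 10² M⁻¹s⁻¹,
k_off = 8.39 × 10⁻⁴ s⁻¹, R_max = 100 RU, six doubling dilutions from
16×K_D, association 0–300 s, dissociation to 600 s, 1 s sampling) represent
a micromolar-affinity lectin–Fc interaction on a standard multi-channel
instrument schedule.

## Permethylated glycan masses

Permethylated N-glycan masses are additive: each residue class contributes
its in-chain (dehydro) elemental mass plus one CH₂ per methylatable
hydroxyl/amide site (Hex 3, HexNAc 3, dHex 2, NeuAc 5), and the molecule
gains one end-group correction — H₂O for the free reducing terminus plus
two terminal CH₂ — and the adduct ion mass ([M+Na]⁺ default, [M+K]⁺
available). The frozen residue table (Hex 204.0998, HexNAc 245.1263,
dHex 174.0892, NeuAc 361.1737 Da; end group 46.0419; Na⁺ 22.9892) is
asserted against two independent elemental routes in the tests — a direct
atomic-mass computation and pyteomics formula masses — to 0.001 Da.
Monoisotopic (not average) masses are used throughout, since reflectron
MALDI-TOF annotation labels monoisotopic peaks; integer comparison rounds
half away from zero. Composition enumeration is exhaustive within bounds
(defaults HexNAc 2–8, Hex 3–12, dHex 0–3, NeuAc 0–4 — NeuGc and
sulfated/phosphorylated classes excluded by default, extendable via a
custom mass table), and peak annotation reports *all* in-tolerance
compositions ranked by absolute error, leaving interpretation to the user:
a large ion can admit both a polylactosamine and a sialylated composition
at integer precision, and which is plausible depends on biological context
the annotator does not have. The default match tolerance of 0.5 Da suits
integer-labelled peak lists; high-resolution data should tighten it.
Core versus antennal fucose is isobaric at MS¹ — `fucose_isomer_masses`
exists to state that explicitly; fragment prediction is out of scope.

## Synthetic data

The generators produce the smallest objects that exercise each analysis
end-to-end with known truth:

- **Hinge structures** — two rigid Cα-only arms of 8 pseudo-residues
  (3.8 Å spacing) meeting at a vertex, built in-plane at the designed angle
  and then given a seeded random rigid motion so nothing is axis-aligned.
  The designed angle is exact in memory; PDB output quantises coordinates
  to 0.001 Å (≈ millidegree effect at these lever arms).
- **Glycan-state trajectories** — a 12-residue pseudo-Cγ2 grid (one heavy
  atom each, 20 Å apart, so contacts cannot occur by accident) plus a
  7-residue pseudo-glycan whose probe residues are placed 2 Å from exactly
  the designed number of grid residues; all other glycan atoms are parked
  120 Å away. Design mode pins the loose-frame count exactly; sampling
  mode draws i.i.d. labels at a given probability. Labels are realizable
  only when loose_contacts ≤ threshold < bound_contacts, enforced at recipe
  construction.
- **Sensorgrams and peak lists** — thin seeded wrappers over the kinetics
  simulator and the mass calculator, with Gaussian RU noise and m/z jitter
  respectively.

What these fixtures do *not* emulate: force-field energetics, solvent,
realistic glycan geometry or flexibility, instrument artifacts (drift,
spikes, bulk shifts), or isotope envelopes. Passing tests therefore
demonstrate the correctness of the *operators* — counting, classification,
fitting, mass arithmetic — under controlled truth, not the behaviour of
real systems; conclusions about real data still require real structures,
trajectories and spectra. All randomness flows through one
`numpy.random.default_rng(seed)` per generator call, making every fixture
bit-reproducible; there is no global random state anywhere in the package.

## Problem sizes in the shipped checks

The test suite and acceptance script run at desk scale by design: 60-atom
random frames (×100) for the contact oracle, 200–2 000-frame synthetic
trajectories for the classifier, six-curve 600-point sensorgram series for
fitting (20 noisy replicates), and exhaustive composition enumeration over
~1 400 candidates. These sizes give the statistical resolution the
assertions need (e.g. a 3-standard-error band of ±3.2 percentage points at
2 000 frames) while keeping a full run under a minute on one CPU.
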