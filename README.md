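# fcbind

Quantitative analyses of how oligomeric IgG Fc scaffolds engage their
receptors. Engineered Fc multimers bind low-affinity inhibitory receptors
(FcRL5, FcγRIIb) and the C-type lectin DC-SIGN with high avidity, and the
structural and biophysical evidence for *how* rests on a handful of
computable quantities. This package implements those computations as a
reusable, tested toolkit for structural immunologists and protein engineers:

- **Interdomain hinge angles** — the D1–D2 hinge of an Fcγ-type receptor,
  measured as the angle subtended at a vertex residue's Cα by two outer
  anchor residues, on single structures or multi-model PDB trajectories.
- **Glycan configuration dynamics** — per-frame classification of an Fc
  N-glycan (Man₅GlcNAc₂ at Asn297) as tightly or loosely Cγ2-associated:
  count the Cγ2 residues with any heavy atom within 3 Å of glycan residues
  2–6; a frame with ≤ 2 such residues is "loose". Trajectory state
  fractions follow directly.
- **Lectin accessibility** — a geometric test of whether a
  carbohydrate-recognition domain, idealised as a 3 nm sphere, can reach a
  mannose through the Fc cavity's 2 × 3.5 nm elliptical entrance.
- **1:1 Langmuir SPR kinetics** — closed-form sensorgram simulation and
  global least-squares fitting of (k_on, k_off, R_max) across a
  doubling-dilution series, with K_D = k_off / k_on always derived from the
  rates (dR/dt = k_on·C·(R_max − R) − k_off·R).
- **Permethylated N-glycan masses** — monoisotopic [M+Na]⁺ m/z of
  permethylated N-glycan compositions (HexNAc / Hex / dHex / NeuAc),
  composition enumeration under bounds, and MALDI-TOF peak-list annotation.
- **Synthetic fixtures** — generators that emit structures with designed
  hinge angles, trajectories with designed state fractions and contact
  counts, noisy sensorgrams and peak lists, each with ground truth, so the
  full pipeline is testable without any external data.

## Worked example

Simulate a noisy doubling-dilution SPR series at micromolar-affinity rates
and refit it globally, then compute permethylated glycan ions:

```python
from fcbind import spr_kinetics as spr, glycomass as gm
from fcbind.synthetic_data import make_sensorgrams

curves, truth, schedule = make_sensorgrams(
    kon=6.68e2, koff=8.39e-4, rmax=100.0, noise_sd=1.0, seed=42
)
fit = spr.fit_langmuir(curves, schedule)
print(f"kon  = {fit.kon:.3g} M^-1 s^-1   (true {truth.kon:.3g})")
print(f"koff = {fit.koff:.3g} s^-1        (true {truth.koff:.3g})")
print(f"KD   = {fit.kd*1e6:.2f} uM          (true {truth.kd*1e6:.2f})")

for comp in ("HexNAc4Hex5dHex1", "HexNAc5Hex6dHex1", "HexNAc6Hex7dHex1"):
    print(comp, "->", f"{gm.permethylated_mz(comp):.2f}")
```

prints

```
kon  = 667 M^-1 s^-1   (true 668)
koff = 0.00084 s^-1        (true 0.000839)
KD   = 1.26 uM          (true 1.26)
HexNAc4Hex5dHex1 -> 2244.12
HexNAc5Hex6dHex1 -> 2693.35
HexNAc6Hex7dHex1 -> 3142.58
```

The fitted rates recover the simulation truth to well within the noise, the
derived K_D is 1.26 µM, and the three core-fucosylated compositions give the
integer ions 2244, 2693 and 3143 — the masses at which such glycans appear
in permethylated MALDI-TOF spectra.

A `fcbind` console script exposes the same operations from the shell
(`fcbind hinge`, `fcbind contacts`, `fcbind glycan-states`,
`fcbind accessibility`, `fcbind spr-sim`, `fcbind spr-fit`, `fcbind mz`,
`fcbind annotate`, `fcbind synth ...`); every subcommand reads and writes
plain-text PDB, TSV and JSON.

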