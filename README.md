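# nucsox

Analysis toolkit for **dynamic integrative modeling (DIM)** of how Sox
pioneer transcription factors recognize their binding motif on nucleosomal
DNA.

Sox-family factors (Sox2, Sox6, Sox11, ...) carry an HMG domain that binds
the DNA **minor groove** at its cognate `5'-TTGT-3'` sequence, reading it in
two coupled ways: *base reading* (base-specific hydrogen bonds by Arg51,
Asn54 and Tyr118) and *shape reading* (the hydrophobic Phe56/Met57 "FM
wedge" widens the minor groove up to **22.5 Å** and bends the duplex).  On
a nucleosome, whether this reading is possible depends on where the motif
sits: positions along the wrapped DNA are indexed by **superhelical
locations** (SHL), counted in ~10-bp steps from the dyad (SHL0) outward.

`nucsox` implements the analysis layer of the DIM protocol as a reusable,
tested library:

| module | what it does |
|---|---|
| `model_io` | PDB structures & multi-model trajectories, atom selections, Watson–Crick duplex inference with a dyad anchor |
| `sequence_design` | engineering the Sox consensus `GGACAATGGAGG` into the Widom-601 sequence, motif scanning, dyad-relative → SHL mapping |
| `geometry` | Kabsch superposition (proper rotations only), **P-RMSD** over the 7-nt recognition window, minor-groove width profiles (raw cross-strand P–P or refined), RMSF → temperature factors |
| `contacts` | per-frame hydrogen-bond / hydrophobic / ionic detection, base-specific classification, barcode matrices and persistence rates |
| `dim_select` | bound-compatible conformer selection (lowest P-RMSD frame) and distance-restraint emission (TSV and CNS/AIR `assign` dialects) for external docking |
| `titration` | footprinting-gel band normalization, biexponential fitting `f1(x) = a·e^(bx) + c·e^(dx)`, and apparent-Kd extraction at the half-level of the signal change |
| `synthetic_data` | seeded generators: fiber B-DNA, controlled groove deformation, thermal/drift trajectories, designed contact probes, noisy titration curves |
| `cli` | `nucsox` command: config-driven pipeline runs and per-stage utilities |

The key metric is the **P-RMSD**: the RMSD of the phosphorus atoms of the
7-nt recognition window (`5'-GACAATG-3'`) after least-squares superposition
onto the Sox-bound DNA reference conformation.  A DNA stretch is
"bound-compatible" when its P-RMSD fluctuates within **0.7–2.2 Å** of that
reference.

## Worked example

```python
from nucsox import sequence_design as sq, synthetic_data as sd, geometry as geo, titration as ti

# 1. where do the engineered Sox sites sit on the nucleosome?
construct = sq.load_construct("Sox6-SHL024")       # 255-bp titration construct
motif = sq.NucleotideSequence(sq.SOX_CONSENSUS)
dyad = sq.scan_motif(construct, motif)[0].start + 4
for hit in sq.scan_motif(construct, motif, dyad_index=dyad):
    center = hit.dyad_relative + len(motif) // 2
    print(f"motif at dyad-relative {hit.dyad_relative:+d} -> SHL {sq.map_shl(center)[1]}")

# 2. does a Sox-bound-like duplex show the groove fingerprint?
duplex = sd.build_bdna(sq.NucleotideSequence("GCGCAAATTTGCGCGCAAATTTGCGCGCAAA"))
dm = sd.default_duplex_map(duplex)
bound = sd.deform_groove(duplex, center=0, span=12, target_width=22.5, duplex_map=dm)
print(f"max minor-groove width: {geo.max_groove_width(bound, dm):.1f} A "
      f"(free duplex: {geo.max_groove_width(duplex, dm):.1f} A)")

# 3. quantify a synthetic footprinting titration
conc = ti.make_dilution_series(1000.0, step=1.5, n_points=12)
series = sd.simulate_titration((1.050, -0.0027, 0.0018, 0.0048), conc,
                               noise_sd=0.02, seed=1)
fit = ti.fit_titration(series, seed=1)
print(f"R2 = {fit.r_squared:.3f}, RMSE = {fit.rmse:.3f}, Kd_app = {fit.kd_app:.0f} nM")
```

prints

```
motif at dyad-relative -4 -> SHL 0
motif at dyad-relative +16 -> SHL 2
motif at dyad-relative +37 -> SHL 4
max minor-groove width: 22.5 A (free duplex: 12.5 A)
R2 = 0.997, RMSE = 0.015, Kd_app = 180 nM
```

Reading the output: the three engineered copies of the consensus fall at
the dyad, SHL2 and SHL4 of the positive DNA arm, exactly one superhelical
turn apart.  The deformation generator reproduces the Sox-bound 22.5 Å
minor-groove opening against a ~12.5 Å relaxed fiber baseline.  The
titration fit meets the published quality gates (R² > 0.97, RMSE < 0.05)
and places the apparent dissociation constant at the concentration where
the footprinting signal has lost half of its assay-range change — an
operational quantity, deliberately not the thermodynamic Kd.

The same chain runs end-to-end from a JSON config:

```sh
nucsox run config.json        # sequence -> trajectory -> P-RMSD/groove/contacts
                              #   -> conformer pick -> restraints -> titration
```

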