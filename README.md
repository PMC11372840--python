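# asdscreen

Screening of drug–polymer thermodynamic compatibility for amorphous solid
dispersions (ASD) with a COSMO-SAC-type activity-coefficient model.

The package covers the full pipeline:

1. **σ-profiles** (`asdscreen.sigma_io`) — parse `.cosmo` surface-segment
   files, spatially average the screening charge densities, and bin them
   into 51-bin σ-profiles split into NHB/OH/OT hydrogen-bonding surface
   classes; read/write a plain-text `.sigma` format.
2. **Polymer replication** (`asdscreen.replication`) — build
   virtual-macromolecule σ-profiles, surface areas and cavity volumes from
   short oligomers by replicating the binned contribution of the central
   monomer unit(s), with unit counts derived from the target molar mass.
3. **Activity model** (`asdscreen.activity_model`) — ln γ as the sum of a
   residual segment-interaction term (misfit + hydrogen-bond exchange over
   the three surface classes), a combinatorial term (Staverman–Guggenheim
   or a free-volume Flory–Huggins form on v − v^HC), and a single-constant
   Margules dispersion term; six switchable model configurations
   (`CS`, `CS^SG`, `CS^FV`, `CS_dsp`, `CS_dsp^SG`, `CS_dsp^FV`).
   Hard-core volumes come from a bond/ring-corrected Bondi-increment scheme.
4. **Equilibria** (`asdscreen.equilibria`) — SLE solubility curves from the
   fusion-property route, LLE binodals by direct isoactivity root-finding or
   the alternating-tangents construction, spinodals, and full phase diagrams
   with UCST/LCST location and AAPS/metastability flags.
5. **Screening** (`asdscreen.screening`) — AAD/AD/AARD deviation statistics
   against experimental solubility tables and compatibility-based polymer
   ranking with optional grade grouping.
6. **Fixtures** (`asdscreen.fixtures`) — deterministic synthetic cavities,
   smooth Gaussian σ-profiles, an analytic symmetric Margules system for
   closed-form equilibrium checks, and the packaged fusion-property table of
   the seven reference APIs (GSF, IBP, IMC, NIF, NPX, PCM, SIM).

## CLI

```bash
# .cosmo -> .sigma (averaging + HB-class binning)
asdscreen sigma molecule.cosmo -o molecule.sigma --hb-classes classes.json

# oligomer -> polymer profile via the replication approach
asdscreen replicate oligomer.cosmo spec.json -o polymer.sigma

# equilibria (component property CSV + σ-profile paths)
asdscreen sle     --component-table components.csv --api NPX --polymer PVPK25 \
                  --t-min 300 --t-max 430 --t-step 1 --outdir out/
asdscreen lle     --component-table components.csv --api IBP --polymer PLGA50 \
                  --outdir out/ --method direct
asdscreen diagram --component-table components.csv --api IBP --polymer PLGA50 \
                  --model CS_dsp^FV --outdir out/

# reports
asdscreen stats --exp exp.csv --calc calc.csv -o report/
asdscreen rank  --predictions predictions.csv -o ranking.csv

# synthetic demo inputs
asdscreen fixtures --seed 1 -o demo/
```

The component table is a CSV with columns
`name, M, v, v_hc, eps, dispersion_class, Tm, dHfus, dCp_a, dCp_b,
sigma_path` (fusion columns empty for non-crystallizable species).
Every solver subcommand writes CSV curves plus a `manifest.json` with a
configuration hash; reruns with the same configuration are bit-identical.

## Formats

* `.cosmo` — keyword-sectioned segment files (`$info`, `$cosmo_data`,
  `$coord_rad`, `$segment_information`) with lengths in Å or atomic units
  as declared by `length_unit`; other dialects are rejected explicitly.
* `.sigma` — commented key/value header (name, area, volume) followed by 51
  rows of `σ  A_nhb  A_oh  A_ot`; legacy 2-column single-class files load
  with all area as NHB.

## Scope

Binary API–polymer systems only; polymers are treated as monodisperse
single molecules; no quantum-chemical calculations, glass-transition
overlays, or kinetics.
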