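# bondheat

Heat-map bond coloring for interpreting linear SVM screening models.

`bondheat` trains a sparse linear max-margin classifier on circular
substructure fingerprints and maps the model's weight vector back onto the
bonds of individual molecules: every fingerprint feature remembers exactly
which bonds it covers (including bonds to attachment points), each bond's
score is the sum of the weights of all feature occurrences covering it, the
scores are normalized to [0,1] — against the whole training set
("full_set") or against the molecule itself ("single_molecule") — and
rendered as a red → orange → green gradient on a 2D depiction. Bonds that
drive a positive prediction come out green, bonds that argue against it red.

## Modules

| module | purpose |
| --- | --- |
| `bondheat.chem_io` | SMILES/SDF parsing into a heavy-atom graph model (RDKit-backed) |
| `bondheat.fingerprint` | explicit-growth circular-substructure fingerprint with full feature→bond provenance |
| `bondheat.model` | liblinear-backed linear SVM, rare-feature filter, nested (two-deep) cross-validation, JSON persistence |
| `bondheat.coloring` | bond/atom scores, both normalization modes, two-part color gradient |
| `bondheat.render` | deterministic SVG depictions and captioned grids |
| `bondheat.synthetic` | seeded libraries with planted activating/deactivating substructures and a recovery metric |
| `bondheat.cli` | `bondheat fingerprint | train | color | synth | render` |

Defaults follow the method's published configuration: fingerprint depth 4,
2^22 hash space, features kept only if they occur in ≥ 3 molecules,
hyperparameter grids log2(C) ∈ {−5..8} and log2(W₋₁) ∈ {−4,−2,0} searched
by inner 2-fold CV inside a 5-fold outer CV repeated twice, and no
fragment-size weight distribution.

## CLI walk-through

```sh
# 1. generate a synthetic labeled library with planted substructures
bondheat synth --n-active 50 --n-inactive 150 --seed 1 --out-dir lib/

# 2. fingerprint it (sparse lines + provenance sidecar)
bondheat fingerprint lib/molecules.sdf --labels lib/labels.csv --out data

# 3. nested cross-validation + final model
bondheat train data.fp --model-out model.json --report-out report.csv

# 4. color molecules of interest and write per-bond CSV + SVGs
bondheat color model.json lib/molecules.sdf \
    --mode single_molecule --csv-out colors.csv --svg-dir svg/

# full_set normalization needs the training set again:
bondheat color model.json query.smi --mode full_set \
    --training lib/molecules.sdf --csv-out colors.csv

# 5. captioned grid (prediction values to 3 decimals)
bondheat render model.json lib/molecules.sdf --out grid.svg
```

## Reproducing published benchmark numbers (tutorial, not CI)

The reference evaluation was reported on the Kazius Ames mutagenicity set
and the MUV virtual-screening sets (AUC ≈ 0.912 on Kazius, 0.900 on MUV548,
0.958 on MUV846). Those datasets are not redistributable here; to reproduce:

1. Download the Kazius SDF (with mutagenicity labels) and/or MUV actives +
   decoys for targets 548/846, and convert labels to a `name,label` CSV
   with labels in {+1, −1}.
2. Standardize structures beforehand (neutralize, canonical tautomer,
   aromatize) — this package applies only RDKit's default sanitization.
3. Run:

   ```sh
   bondheat fingerprint kazius.sdf --labels kazius_labels.csv --out kazius
   bondheat train kazius.fp --model-out kazius_model.json --report-out kazius_cv.csv
   ```

   The mean AUC in `kazius_cv.csv` should land near the published values;
   exact agreement is not expected (different standardizer and solver
   internals). For MUV-sized sets expect the full grid search to take a
   while; `--quick-grid` gives a fast approximation.

## Notes

- Feature ids are stable FNV-1a hashes of canonical substructure encodings,
  so saved models can be applied to newly fingerprinted molecules; a model
  refuses fingerprints computed with a different depth/hash-space config.
- Hash collisions are handled as the method prescribes: a colliding id's
  weight is attributed to **all** bond sets that hash to it, and the
  collision fraction is logged by `bondheat fingerprint`.
- All outputs (SVG, CSV, JSON, SDF) are plain text and byte-deterministic
  for fixed seeds.
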