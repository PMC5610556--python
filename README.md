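# tetrakey

Morphometric indices, dichotomous identification keys, and checklist
analytics for the Indian fauna of the ant genus *Tetramorium*.

The package encodes, as data:

- the **14 standard linear worker measurements** (mm) and the
  **13 ratio indices** derived from them (`OI = EL/HW × 100`, `CI`,
  `SI`, `DMI`, `LMI`, `PSLI`, `PeNI`, `LPeI`, `DPeI`, `PpNI`, `LPpI`,
  `DPpI`, `PPI`);
- **three dichotomous keys** (the 12-couplet key to the 13 Indian
  species groups, and the species-level keys to the *inglebyi* and
  *tonganum* groups), each as a validated JSON document with character
  vocabulary and predicate expressions;
- the **species checklist** (42 valid species, 27 endemics, 2 exotics,
  2 excluded records) with endemic/exotic flags and comments;
- the **species-group diagnoses** as predicates/state templates over
  the key's characters;
- the **published worker measurement ranges** of the two recently
  described Andaman species (*jarawa*, *krishnani*), including their
  printed index ranges and type localities.

On top of that data it provides:

- `compute_indices` / `round_index` — raw ratios and the
  reporting-precision rule used by the printed tables;
- `index_interval` / `consistency_check` — interval arithmetic under
  rounding uncertainty. Published indices were computed from
  unpublished 3-decimal measurements, so recomputing from printed
  2-decimal values reproduces only 9 of the 26 printed holotype
  indices; the consistency checker instead asks whether a printed
  value's rounding band intersects the feasible interval of the printed
  measurements (all 26 pass at h = 0.005 mm);
- `load_key` / `validate_key` / `traverse` / `traverse_partial` —
  structural diagnostics (reachability, acyclicity, lead overlap/gap
  warnings), strict traversal, and exact set-valued traversal under
  unknown character states;
- `load_species_table` / `fauna_summary` / `apply_diagnosis` /
  `match_specimen` — checklist analytics and specimen-to-species
  matching against the published ranges;
- `tetrakey.synth` — seeded generators for specimen tables and state
  vectors with ground truth, for property testing.

## CLI

```sh
tetrakey summary                               # checklist totals
tetrakey --format json summary
tetrakey measure specimens.csv                 # 13 indices per specimen
tetrakey measure specimens.csv --out idx.csv --raw
tetrakey check specimens.csv --species jarawa  # consistency vs ranges
tetrakey key validate india_species_groups
tetrakey key run tonganum_group states.csv     # strict traversal
tetrakey key run tonganum_group states.csv --partial
tetrakey match specimens.csv                   # rank species with ranges
tetrakey --seed 7 synth specimens --species jarawa --n 100 --out fixtures/
tetrakey --seed 7 synth states --group inglebyi --n 50 --unknown-rate 0.3 --out fixtures/
```

Global options: `--halfwidth` (rounding half-width h in mm, default
0.005), `--seed`, `--format {text,csv,json}`, `--verbose`.
Exit codes: 0 success, 2 validation error, 3 identification conflict.

Specimen CSV header (fixed order, UTF-8, `.` decimal separator):

```
specimen_id, taxon_hint, HL, HW, SL, EL, PH, PW, WL, PSL, PTL, PTH, PTW,
PPL, PPH, PPW, latitude, longitude, locality, collection_note
```

Empty measurement cells mean "not measured"; derived indices come out
absent rather than erroring. Coordinates accept signed decimal degrees
or hemisphere-suffixed values (`11.975817 N`).

State-vector CSV: `specimen_id` plus one column per character id of the
chosen key; empty cells mean unknown. The key file format is described
by `src/tetrakey/data/key_schema.json`.

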