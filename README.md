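# mappkit

Downstream analysis of MHC class II immunopeptidomics (MAPPs-style) donor
panels for therapeutic antibodies:

- **PSM filtering** — charge-dependent XCorr confidence tiers (medium
  windows 2.0–2.3 / 2.5–3.0 / 2.8–3.5 for charges 2 / 3 / ≥4, high strictly
  above), a ≤4-modifications cap, and concatenated target-decoy FDR
  (q ≤ 0.01 by default).
- **Peptide mapping** — no-enzyme substring placement of accepted peptides
  onto heavy/light chains (1-based inclusive coordinates), CDR-overlap
  annotation, uniqueness vs a background proteome (optionally treating
  I/L as equivalent), and length statistics.
- **Nested-set clustering** — greedy grouping of peptides with ragged N/C
  termini around a shared consensus core (default core requirement:
  9 residues), per-cluster donor presentation frequencies, cross-run
  cluster matching.
- **Panel metrics** — per-sample HC/LC/total peptide counts and
  percent-therapeutic (2 significant figures), modification donor
  frequencies, replicate concordance (cluster-level Jaccard), report
  bundle (JSON + TSV).
- **Heat maps** — deterministic SVG coverage maps: residue axis with blue
  CDR bands, peptide blocks shaded by confidence tier, purple Met-ox
  marks, yellow localized / red unlocalized deamidation.
- **Synthetic panels** — a fully seeded generator producing PSM tables,
  therapeutic FASTA + CDR sidecar, background proteome, and complete
  ground truth (planted cores, presentation matrix, per-row true/false
  labels, modification events) so every stage is testable offline.

## CLI

```bash
# generate a synthetic panel (inputs + truth tables)
mappkit simulate --seed 1 --out panel/

# stage by stage
mappkit filter --psm panel/psm/D01_r1.tsv --out accepted.tsv
mappkit map --psm accepted.tsv --therapeutic panel/therapeutic.fasta \
    --regions panel/regions.tsv --background panel/background.fasta \
    --out mapped.tsv
mappkit cluster --mapped mapped.tsv --out clusters.tsv
mappkit summarize --psm accepted.tsv --mapped mapped.tsv --outdir report/
mappkit render --mapped mapped.tsv --therapeutic panel/therapeutic.fasta \
    --regions panel/regions.tsv --out coverage.svg

# end to end from a YAML config
mappkit run --config pipeline.yaml
```

A minimal `pipeline.yaml`:

```yaml
seed: 1
output_dir: out
simulation:           # or: therapeutic_fasta/regions/background_fasta/psm_tables
  n_donors: 7
filter:
  fdr_threshold: 0.01
  max_mods: 4
  tier_floor: medium
clustering:
  min_core_overlap: 9
match_mode: exact
```

Exit codes: 0 success (including empty results), 2 configuration error,
3 data-validation error.

## File formats

- **PSM TSV** (columns, exact order): `sample_id donor_id day analyst
  peptide charge xcorr mods proteins is_decoy`; `mods` uses
  `<residue><pos>(<ox|deam>)` tokens, `?` marks an unlocalized site,
  e.g. `M4(ox);N?(deam)`.
- **Therapeutic definition**: FASTA with `|HC` / `|LC` header tokens plus a
  tab-separated regions sidecar `chain_id region_name start end`
  (1-based inclusive).
- **Report bundle**: `summary.json`, `samples.tsv`, `clusters.tsv`,
  `frequencies.tsv`, `lengths.tsv`, per-sample SVG heat maps, and a
  `manifest.json` with config hash and input checksums.

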