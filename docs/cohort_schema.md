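# Cohort fixture schema

`src/secondhit/data/cohort.json` transcribes the 29-family study cohort
(families A–AC). It is validated on load by the pydantic models in
`secondhit.cohort`; editing it into an invalid state raises a
`CohortSchemaError` naming the offending family.

## Top level

```json
{"families": [ <family>, ... ]}
```

## Family entry

| field | type | meaning |
| --- | --- | --- |
| `family_id` | str | family letter (A–AC) |
| `index_id` | str | index patient within the pedigree (e.g. "II:1") |
| `diagnosis` | enum | `arRP`, `sRP`, `LCA`, `STGD`, `USH`, `COD` |
| `phenotype_notes` | str | free-text clinical remarks as printed |
| `inheritance` | enum | `autosomal-recessive` or `simplex` |
| `relatives_available` | bool | segregation analysis possible |
| `prior_variant_ids` | list | ids of the previously known monoallelic variant(s); empty for the four previously unstudied families |
| `candidates` | list | variant records (below) |
| `printed_status` | enum | the published per-family outcome (`solved` / `candidate` / `unsolved`); transcription only — the engine never reads it |
| `printed_status_gene` | str? | gene named with the published outcome |
| `provenance` | str | table row / figure the entry was transcribed from |

## Variant record

Fields follow `secondhit.variants.VariantRecord`: `variant_id` (the
printed M#/m# label), `gene`, `hgvs_c`/`hgvs_p` kept verbatim including
printed idiosyncrasies, `consequence`, `zygosity`, `dp`/`fs`, a `maf`
map (database → frequency), optional `splice` scores, `db_label` with
optional `conflicting_majority`, `protein_predictions`, `novel`, and
`segregation` (`consistent` / `inconsistent` / `unavailable`; the three
deep-intronic variants found in cis with a prior variant are
`inconsistent`).

## Transcription notes and synthetic stand-ins

* **Novelty flags.** Six causal variants are unambiguously marked novel
  in the source table (M2, M7, M8, M16, M21, M23) while the overall
  novel count is stated as 8. The fixture additionally pins **M13**
  (no literature citation; its HGMD label is kept as printed) and
  **M12** as novel — these two assignments are inferred, not printed.
* **Label collision.** The label "m33" is used in the source both for
  USH2A p.Asp1788Gly (family S) and for a deep-intronic USH2A
  duplication in family B; the fixture keeps `m33` for the family-S
  variant and renames family B's to `m33b`.
* **Synthetic MAF values.** Only two population frequencies are printed
  (m4: 0.019; m6: 0.029, both 1000G) — both above the 0.015 screen. All
  other `maf` entries are plausible synthetic stand-ins consistent with
  each variant surviving the screen.
* **Synthetic splice scores.** The source reports qualitative predictor
  outcomes ("New donor", "No impact", …). The numeric `splice` score
  pairs are synthetic stand-ins chosen to reproduce those qualitative
  outcomes under the packaged thresholds.
* **DP/FS.** Not printed per variant; populated with passing values
  (CNV alleles carry none).
* **Database labels** condense the printed ClinVar/LOVD/HGMD columns;
  for conflicting-interpretation entries `conflicting_majority` records
  the printed submission breakdown's majority (e.g. M9:
  Pathogenic 7 / Likely pathogenic 6 / VUS 2 → `pathogenic`; m6:
  benign-leaning → `benign`; m10: balanced → `mixed`).
* **Family H** is recorded with its printed phenotype (arRP with
  sensorineural hearing loss) although the hearing loss likely has a
  separate cause; the diagnosis class remains `arRP`.
* **Family T** carries prior variants in two genes (ABCA4 and CEP290);
  `prior_variant_ids` lists the ABCA4 variant first, and marginal counts
  by prior gene use the first entry.
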