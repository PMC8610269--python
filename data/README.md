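# Per-case data

Real per-case clinicopathologic + expression data are not redistributable
with this package. To run the printed-value reproduction (the
spreadsheet-driven test in `tests/test_acceptance.py` and the `reproduce`
CLI command), place the study's supplementary per-case workbook here as

    data/s2_cohorts.xls

together with an optional column-mapping YAML `data/s2_mapping.yaml` of the
form

```yaml
columns:
  # spreadsheet column -> canonical field
  "Patient ID": subject_id
  "Cohort": cohort                 # 1 (IHC) or 2 (IF)
  "Group": group                   # tumor / benign
  "Stroma H-score": stroma_h
  "Epithelium H-score": epithelium_h
  "Stroma AQUA": stroma_aqua
  "Epithelium AQUA": epithelium_aqua
  "In both cohorts": in_both_cohorts
  "OS months": os_months
  "OS event": os_event
  "LVI": lvi
```

Canonical fields the reproduction consumes: `cohort`, `group`, `stroma_h`,
`epithelium_h`, `stroma_aqua`, `epithelium_aqua`, `in_both_cohorts`,
`os_months`, `os_event`, `lvi`. Additional clinical columns
(age, stage, grade, response fields, dates) follow the names in
`cavquant.simulate.generate_cohort` output and enable the full subgroup
tables via `cavquant reproduce`.
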