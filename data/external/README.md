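# External data (not bundled)

Place the deposited drug–indication mapping files here to enable the
published-statistics acceptance targets (t1–t5) and the corresponding
tests:

- `ctd_mapping.tsv` — TSV with header, columns `drug_id`, `indication_id`
- `ttd_mapping.tsv` — same format

Source: http://compbio.buffalo.edu/data/mc_cando_benchmarking2

Without these files, `scripts/acceptance.py` writes an empty report and the
deposited-mapping tests in `tests/test_acceptance.py` are skipped.
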