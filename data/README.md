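# Study inputs (not bundled)

Two acceptance checks in `tests/test_acceptance.py` analyse the published
study's own raw inputs, which are not redistributable here:

- `s1_table.csv` + `s1_schema.json` — the 269-specimen raw morphometric and
  meristic table (export the deposited XLSX supplement to CSV with a
  `specimen_id` column and a `group` column; the schema JSON maps each
  variable to `SL`, `morphometric_SL`, `morphometric_HL` or `meristic`).
- `coi_barcodes.fasta` — the 77 aligned COI barcodes (GenBank accessions
  MG282922–MG283000), headers formatted `id|species`.

Until these files are supplied, those two checks fail; everything else in the
test suite is self-contained.
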