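# Published supplementary tables (drop-in location)

The original study deposited its Boolean regulation rules and the binary
spatial module-state table only as journal supplementary material; neither
is redistributed here.  To run the checks that compare this implementation
against the published attractor landscape, transcribe them into this
directory:

- `gmn_rules.txt` — the 12 module regulation rules in the
  "targets, factors" dialect, one line per module, e.g.

      targets, factors
      M1, !M9 & M10 & !M12
      ...

- `state_table.tsv` — the 12 x 14 binary module-state table
  (rows `M1`..`M12`, columns the 13 ordered positions `A1`..`B7` plus the
  duplicated terminal column `B7*`), tab-separated with a `module` index
  column, as written by `BinaryStateTable.to_tsv`.

Without these files the corresponding checks in
`tests/test_acceptance.py` report the missing input and fail; every other
test runs on generated data.
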