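# sheetready

Lint tabular spreadsheet data against 11 best-practices rules, export
archive-ready CSV, build a 47-element EML metadata record, generate data
citations and ARK identifiers, and package datasets for repository
deposit — as a Python library plus a `sheetready` CLI.

Input formats are `.xlsx` (Office Open XML) and RFC 4180 `.csv`. Nothing
touches the network: identifiers come from a local stateful ARK minter
(test NAAN 99999) and deposits go to a filesystem repository adapter.

## The 11 rules

| # | rule id | scope | auto-fix |
|---|---------|-------|----------|
| 1 | `embedded_objects` (charts/pictures/pivots) | sheet | yes |
| 2 | `embedded_comments` | sheet | yes |
| 3 | `commas` in text cells | table regions | no |
| 4 | `special_characters` (non alphanumeric-safe) | table regions | no |
| 5 | `color_coding` (fill/font colors) | table regions | yes |
| 6 | `mixed_types` within a column | table regions | no |
| 7 | `non_contiguous` (multiple tables per sheet) | sheet | no |
| 8 | `merged_cells` | sheet | yes |
| 9 | `blank_cells` inside a table | table regions | no |
| 10 | `header_problem` (absent / duplicated / stacked) | table regions | no |
| 11 | `multiple_sheets` (informational) | workbook | yes (export splits) |

Table regions are maximal contiguous blocks found by recursively
splitting the used range at fully empty rows/columns; headers are
inferred from all-text, gap-free, unique-label top rows.

## CLI

```sh
sheetready fixture --defects merged_cells,commas --seed 1 --out wb.xlsx
sheetready check wb.xlsx --report json          # exit 0; --strict -> 1 on issues
sheetready export wb.xlsx --out csvs/ --fix     # one CSV per non-empty sheet
sheetready metadata init wb.xlsx --meta meta.txt   # pre-populated template
sheetready metadata validate --meta meta.txt
sheetready cite --meta meta.txt --year 2012 --format ris
sheetready mint --state minter.txt
sheetready package wb.xlsx --meta meta.txt --out pkg/ --state minter.txt
sheetready deposit pkg/ --repo fs:/srv/repo --state minter.txt
sheetready metadata embed wb.xlsx --meta meta.txt --out described.xlsx
```

The metadata entry file is plain `key: value` text (keys listed by
`metadata init`; keywords separated by `;`, column attributes as
`attribute.<n>.<field>`). A deposit package contains `data/*.csv`,
`eml.xml`, `citation.{ris,bib,xml}`, `techmd.json` and a BagIt-style
`manifest-sha256.txt`; the filesystem adapter re-verifies the manifest
after copying and removes partial transfers on mismatch.

## Library sketch

```python
from sheetready import (read_workbook, run_all_checks, export_csv,
                        generate_fixture, prepopulate, to_eml)

wb = read_workbook("survey.xlsx")
report = run_all_checks(wb)           # CheckReport with located issues
paths = export_csv(wb, "out/")        # splits multi-sheet workbooks
```

Modules: `model` (neutral workbook model), `io` (.xlsx/CSV read/write),
`regions` (table + header detection), `checks` (the 11 rules),
`export` (CSV export + bulk remediation), `metadata` (schema,
validation, EML, metadata-tab embedding), `citation` (citations + ARK
minting), `deposit` (readiness, packaging, repository adapter),
`fixtures` (deterministic defect-injection generator), `cli`.

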