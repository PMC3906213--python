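# File formats

All files are plain-text TSV/CSV with explicit headers. Floats are
written with 6 decimal places unless noted; round-trips are lossless at
that precision. Missing values are not permitted in signal files.

## Signals (`signals.tsv`, TSV)

One row per probe; per sample a triplet of columns.

| column | type | description |
| --- | --- | --- |
| `probe_id` | string | unique probe identifier (e.g. `cg00000123`) |
| `<sample>.meth` | float ≥ 0 | methylated signal intensity |
| `<sample>.unmeth` | float ≥ 0 | unmethylated signal intensity |
| `<sample>.detp` | float in [0, 1] | detection p-value |

All three layers must be present for every sample; duplicate probe ids,
negative signals and missing values are hard errors (reported with the
offending probe/sample and line number where applicable).

## Probe manifest (`manifest.tsv`, TSV)

| column | type | description |
| --- | --- | --- |
| `probe_id` | string | unique |
| `chromosome` | label | one of 1–22, X, Y |
| `position` | int > 0 | 1-based coordinate (genome build is opaque metadata) |
| `gene` | string | nearest gene, may be empty |
| `blacklisted` | bool | non-specific / unreliable probe flag |

## Sample sheet (`sample_sheet.csv`, CSV)

| column | type | description |
| --- | --- | --- |
| `sample_id` | string | unique |
| `pair_id` | string | each value occurs exactly twice |
| `member` | `A`/`B` | twin label within the pair |
| `sex` | `M`/`F` | shared within a pair |
| `group` | label | `discordant_asd`, `concordant_asd`, `discordant_social`, `discordant_rrbi`, `discordant_communication`, `concordant_unaffected` |
| `asd_affected`, `social_affected`, `rrbi_affected`, `communication_affected` | bool | per-domain affected flags |
| `familial_class` | `sporadic` / `familial` / empty | affected member of a discordant-ASD pair / member of a concordant-ASD pair |

Load-time checks: a discordant pair has exactly one affected member for
its focal domain; concordant pairs have matching flags.

## Trait scores (`trait_scores.csv`, CSV)

| column | type | description |
| --- | --- | --- |
| `sample_id` | string | |
| `total` | int 0–31 | sum of the three subscales |
| `social` | int 0–12 | |
| `rrbi` | int 0–7 | restricted repetitive behaviours and interests |
| `communication` | int 0–12 | |
| `at_risk` | bool | exactly `total >= 15` |

## Truth table (`truth_table.tsv`, TSV)

One row per planted effect: `probe_id`, `mechanism`
(`dmr`/`private`/`trait`), `effect` (Δβ or target r), `design`,
`pair_id`, `trait` (unused fields empty).

## Beta / transformed matrices (`beta.tsv`, `transformed.tsv`, TSV)

`probe_id` followed by one float column per sample.

## Ranked DMR table (`dmr_<design>.tsv`, TSV)

Leading columns mirror the published table layout, extras follow:

`rank`, `probe_id`, `gene`, `chromosome`, `position`,
`mean_delta_beta`, `p_value`, `t`, `p_rank`, `magnitude_rank`,
`combined_score`, `bonferroni_significant`, `design`.

## Family hits (`family_hits.tsv`, TSV)

`probe_id`, `pair_id`, `delta_beta`, `direction` (`hyper`/`hypo`),
`shared_with` (comma-separated pair ids exceeding the threshold at the
same probe with the same sign).

## Trait correlation (`trait_corr_<trait>.tsv`, TSV)

`probe_id`, `trait`, `n`, `r`, `p_value` and — when a sensitivity
exclusion was run — `n_excluded`, `r_excluded`, `p_value_excluded`,
`excluded_pairs`.

## BED export (`dmr_<design>_top<k>.bed`)

0-based half-open, one interval per CpG: `chr<chromosome>`,
`position−1`, `position`, name = probe id, score = ⌊|mean Δβ|·1000⌋.

## Filter report (`filter_report.tsv`, TSV)

`probe_id`, `reason` (`detection`, `blacklist`, `undefined_beta`); one
row per removed probe, each probe under the first rule that removed it.

## VST reference (`vst_reference.tsv`, TSV)

The fitted transform snapshot: `beta`,`ecdf` (probit strategy) or
`beta`,`transformed` (variance strategy).

## Output manifest (`output_manifest.json`)

JSON object mapping every output file name to its SHA-256 content hash;
reruns with the same configuration and seed are byte-identical.
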