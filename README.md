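# occaudit

Taxonomic-certainty auditing of species occurrence databases, with an
uncertainty-aware compilation of mixed reviewed/online spatial databases.

Occurrence databases mix three sources of taxonomic uncertainty: outdated
names, changed taxon concepts, and plain misidentification. Given a database
whose records carry both the *original* determination and a *revised*
determination by a reference taxonomist, `occaudit`:

- **classifies** every record as correct, misidentification, soft taxonomic
  change (resolvable by name/concept harmonization), hard taxonomic change
  (unresolvable without the specimen), or not identified — driven by an
  editable concept-rule table, after removing records determined by the
  reference taxonomists themselves (circularity filter);
- **summarizes** error patterns as classification matrices and per-group
  rate tables with two-level chi-squared goodness-of-fit tests and
  significance codes, plus a binomial GLM of error probability on species
  and the number of congeners per region;
- **compiles** a merged spatial database: online records are kept only from
  regions where a single congener occurs, thinned with a per-species
  distance buffer (10 km continental / 1 km island by default), and merged
  with the reviewed records;
- **simulates** occurrence databases with known per-species error structure
  and ground-truth labels for end-to-end and recovery testing.

The package ships a worked example for the six west-European ivy species
(*Hedera*): a 1011-record classification-matrix fixture, the matching
concept-rule book, and the region table of co-occurring congener counts.

## CLI

```sh
# expand the packaged classification matrix into a record-level file
occaudit expand-fixture --seed 1 --out occurrences.csv

# classify + matrix + rate tables
occaudit audit --input occurrences.csv --out-dir out/

# rate tables / GLM on their own
occaudit stats --input occurrences.csv --group species --glm

# merged spatial database (reviewed + filtered/thinned online records)
occaudit merge --reviewed reviewed.csv --online online.csv --out-dir out/ \
    --buffer-continental 10000 --buffer-island 1000

# synthetic benchmark data with truth labels
occaudit simulate --real-structure --n-per-species 2000 --seed 7 \
    --out sim.csv --truth-out truth.csv
```

Exit codes: 0 success, 2 configuration error, 3 data validation error.

## Library sketch

```python
import occaudit as oa

kb = oa.load_concept_rules()
matrix = oa.load_classification_matrix()
records = oa.expand_matrix(matrix, seed=1)
kept, excluded = oa.filter_circularity(records)
classified = oa.classify_records(kept, kb)
print(oa.rate_table(classified, "species"))
```

## Data files

- `src/occaudit/data/classification_matrix.csv` — original × revised
  identification counts for the reviewed *Hedera* database (N = 1011).
- `src/occaudit/data/concept_rules.csv` — (original name, revised species)
  → category/change-type rules; validated at load.
- `src/occaudit/data/region_uncertainty.csv` — region → number of
  co-occurring congeners; island group takes precedence over country, and
  unlisted regions default to a single congener.
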