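# Template run configuration for the deposited redacted injection database.
#
# Copy next to a local download of the database (it is not redistributed with
# this package), fill in the actual source column names and the vocabulary /
# region tables from the deposited analysis script, and run:
#
#   optoaudit report --config data/deposited/config.toml --out-dir report/
#
# The column names below are placeholders; the deposited spreadsheet's exact
# headers must be checked against the file.

input_path = "data/deposited/redacted_database.csv"
out_dir = "deposited_report"
key_fields = ["lab", "animal", "region"]
strict = true

[columns]
lab = "lab"
animal = "animal"
region = "region"
vector = "vector"
histology = "histology"
physiology = "physiology"
behavior = "behavior"

# Extra raw-outcome spellings found in the file, mapped onto the four-level
# scale (MISSING, FAILED, WEAK, STRONG). The defaults already cover
# strong/weak/mixed/partial/yes/success/no/none/failed/failure and NA-likes.
[outcome_map]
# "strong effect" = "STRONG"

# Lab-specific region spellings -> canonical label. Ships empty by default:
# merges must come from the deposited analysis, not be invented here.
[region_synonyms]
# "primary visual cortex" = "V1"

# Canonical region -> PRIMARY_SENSORIMOTOR or OTHER, for the region breakdown.
[region_classes]
# V1 = "PRIMARY_SENSORIMOTOR"
# AMY = "OTHER"
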