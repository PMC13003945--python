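# Column-name dictionary for running the statistical pipeline on the
# published participant-level dataset (place it, exported to CSV, at
# data/supplementary_dataset.csv).
#
# Keys are the column headers as they appear in the deposited file; values
# are this package's canonical variable names (see djpls.features
# VARIABLE_UNITS). Columns already using canonical names need no entry;
# unmapped, non-canonical columns are ignored with a warning.
#
# The deposited file is not redistributed in this repository; fill the
# mapping in after downloading the study's supplementary dataset.
columns: {}
# example:
#   "contact time (s)": "CT"
#   "jump height (m)": "Ht"
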