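# Default ICD-9/10 code set for querying suicidal thoughts and behaviors
# from structured diagnosis data.
#
# This list is a reconstruction assembled from the codes commonly used
# for STB phenotyping (suicidal ideation, suicide attempt / intentional
# self-harm, personal history of self-harm); edit or replace it to match
# institutional practice. Entries are matched by prefix after removing
# the dot; "X71-X83"-style entries match any code whose three-character
# category falls in the range.

code_set_version: "1.0"
icd10:
  - R45.851     # suicidal ideation
  - T14.91      # suicide attempt
  - X71-X83     # intentional self-harm
  - Z91.5       # personal history of self-harm
icd9:
  - V62.84      # suicidal ideation
  - E950-E959   # suicide and self-inflicted injury
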