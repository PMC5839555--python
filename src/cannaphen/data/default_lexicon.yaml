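# Default marijuana-mention search lexicon.
# Whole-word, case-insensitive matching; disabled terms are retained for
# audit and can be switched on in a copy of this file.
terms:
  - surface: marijuana
    enabled: true
    note: most frequent spelled-out term in progress notes
  - surface: cannabis
    enabled: true
    note: clinical/botanical synonym; does not hit "cannabinoid" (whole-word rule)
  - surface: mjx
    enabled: true
    note: local chart shorthand for marijuana
  - surface: mj
    enabled: false
    note: discarded — overlaps with abbreviations for temporomandibular joint (TMJ)
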