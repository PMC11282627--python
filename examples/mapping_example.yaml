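# MappingConfig for `delivcare harmonize`: per-survey code maps plus
# unit and boundary conventions. Codes not listed recode to "missing"
# and are logged. "private_hospital"/"private_clinic" count as hospital.
surveys:
  SVY1:
    place:
      11: home
      21: lower
      26: lower
      31: hospital
      36: private_clinic
    attendant:
      1: skilled
      2: skilled
      3: unskilled
  "*":            # fallback for surveys without their own section
    place:
      home: home
      lower: lower
      hospital: hospital
    attendant:
      skilled: skilled
      unskilled: unskilled

# Duration units, in hours per unit (used for stay and postnatal timing).
unit_hours:
  h: 1
  hours: 1
  d: 24
  days: 24

# Boundary conventions (defaults shown).
stay_cutoff_hours: 24
stay_cutoff_inclusive: true
pnc_cutoff_hours: 48
pnc_cutoff_inclusive: true
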