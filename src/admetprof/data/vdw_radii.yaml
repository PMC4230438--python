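# Bondi van der Waals radii, Angstrom.  Elements absent from the table fall back
# to the generic 1.70 A carbon radius (a warning is logged).
version: 1
radii:
  H: 1.20
  He: 1.40
  C: 1.70
  N: 1.55
  O: 1.52
  F: 1.47
  Ne: 1.54
  Si: 2.10
  P: 1.80
  S: 1.80
  Cl: 1.75
  Ar: 1.88
  As: 1.85
  Se: 1.90
  Br: 1.85
  Kr: 2.02
  Te: 2.06
  I: 1.98
  Xe: 2.16
default: 1.70
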