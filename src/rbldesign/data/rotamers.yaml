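# Backbone-independent rotamer table: common chi-angle modes (degrees)
# per residue type, for geometric feasibility scanning of buttressing
# placements.  A compact substitute for a full backbone-dependent
# rotamer library.
rotamers:
  N:   # Asn: chi1, chi2
    - [-177, -30]
    - [-177, 30]
    - [-177, 90]
    - [-177, -90]
    - [-65, -20]
    - [-65, 40]
    - [-65, 100]
    - [-65, -80]
    - [-65, 160]
    - [63, -20]
    - [63, 40]
    - [63, -80]
  D:   # Asp: chi1, chi2
    - [-177, 0]
    - [-177, 60]
    - [-177, -60]
    - [-70, -15]
    - [-70, 45]
    - [-70, -60]
    - [62, 0]
    - [62, 60]
  Q:   # Gln: chi1, chi2, chi3
    - [-177, 65, -20]
    - [-177, 65, 60]
    - [-177, 180, 0]
    - [-177, 180, 60]
    - [-177, 180, -60]
    - [-67, 180, -25]
    - [-67, 180, 30]
    - [-67, 180, 90]
    - [-67, -65, -40]
    - [-67, -65, 30]
    - [70, 180, 0]
    - [70, 180, 60]
  H:   # His: chi1, chi2
    - [-177, -165]
    - [-177, -80]
    - [-177, 60]
    - [-65, -70]
    - [-65, 80]
    - [-65, 165]
    - [62, -75]
    - [62, 80]
  V:   # Val: chi1
    - [175]
    - [-60]
    - [63]
  L:   # Leu: chi1, chi2
    - [-65, 175]
    - [-177, 65]
    - [-85, 65]
    - [-65, 65]
  I:   # Ile: chi1, chi2
    - [-65, 170]
    - [-177, 170]
    - [-65, -60]
    - [62, 170]
  M:   # Met: chi1, chi2, chi3
    - [-65, 180, 75]
    - [-65, 180, -75]
    - [-65, 180, 180]
    - [-177, 180, 75]
    - [-177, 180, 180]
    - [-65, -65, 100]
  F:   # Phe: chi1, chi2
    - [-65, 90]
    - [-177, 80]
    - [62, 90]
    - [-65, -30]
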