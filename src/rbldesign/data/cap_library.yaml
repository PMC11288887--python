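schema_version: 1
kind: helix_cap
cluster_radius: 0.63
counts:
- 1
motifs:
- kind: helix_cap
  cluster_id: 0
  source: fixture_helix_with_cap len=10:10
  torsions:
  - - -29.07
    - -25.17
    - -180.0
  - - -145.07
    - 66.97
    - -180.0
  - - -90.0
    - 120.0
    - 180.0
  - - -120.0
    - 130.0
    - 180.0
  coords:
  - - -1.458
    - -0.0
    - -0.0
  - - 0.0
    - 0.0
    - 0.0
  - - 0.5515
    - 1.4218
    - -0.0
  - - 1.6716
    - 1.6634
    - 0.4497
  - - -0.2425
    - 2.3591
    - -0.5072
  - - 0.1644
    - 3.7579
    - -0.5666
  - - -1.024
    - 4.6878
    - -0.3458
  - - -1.4372
    - 5.409
    - -1.2537
  - - -1.5691
    - 4.6657
    - 0.8661
  - - -2.7103
    - 5.5061
    - 1.2083
  - - -2.257
    - 6.8558
    - 1.7546
  - - -1.5637
    - 6.9244
    - 2.7694
  - - -2.6533
    - 7.927
    - 1.075
  - - -2.2889
    - 9.2761
    - 1.4906
  - - -3.5273
    - 10.1155
    - 1.7862
  - - -4.455
    - 10.1762
    - 0.9793
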