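schema_version: 1
kind: beta_turn
cluster_radius: 0.63
counts:
- 4
- 4
- 4
- 4
motifs:
- kind: beta_turn
  cluster_id: 0
  source: turn_I:0
  torsions:
  - - .nan
    - 135.0
    - 180.0
  - - -60.0
    - -30.0
    - 180.0
  - - -90.0
    - 0.0
    - -180.0
  - - -120.0
    - 130.0
    - 180.0
  coords:
  - - -1.458
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 0.0
  - - 0.5515
    - 1.4218
    - 0.0
  - - 0.0823
    - 2.2798
    - -0.7477
  - - 1.5498
    - 1.6639
    - 0.8432
  - - 2.1667
    - 2.9813
    - 0.942
  - - 2.77
    - 3.4092
    - -0.3917
  - - 2.8356
    - 4.5988
    - -0.701
  - - 3.2093
    - 2.4316
    - -1.1775
  - - 3.8077
    - 2.7049
    - -2.4787
  - - 2.7517
    - 2.7209
    - -3.5789
  - - 3.0647
    - 2.9358
    - -4.7499
  - - 1.5003
    - 2.4921
    - -3.1944
  - - 0.3964
    - 2.4797
    - -4.1468
  - - -0.6418
    - 3.542
    - -3.8014
  - - -1.0921
    - 3.6356
    - -2.6595
- kind: beta_turn
  cluster_id: 1
  source: turn_Ip:0
  torsions:
  - - .nan
    - 34.7513
    - 180.0
  - - 59.1594
    - 25.7723
    - 180.0
  - - 92.0803
    - -3.5734
    - 180.0
  - - -115.1828
    - 126.6058
    - 180.0
  coords:
  - - -1.458
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 0.0
  - - 0.5515
    - 1.4218
    - 0.0
  - - 1.5894
    - 1.6953
    - -0.6027
  - - -0.1498
    - 2.3232
    - 0.6797
  - - 0.268
    - 3.7177
    - 0.7594
  - - 0.3583
    - 4.3464
    - -0.6271
  - - 1.1063
    - 5.3009
    - -0.8389
  - - -0.4085
    - 3.805
    - -1.5679
  - - -0.4164
    - 4.3115
    - -2.9351
  - - 0.5944
    - 3.5703
    - -3.8037
  - - 0.6885
    - 3.812
    - -5.0071
  - - 1.3484
    - 2.6671
    - -3.1857
  - - 2.3532
    - 1.8893
    - -3.9007
  - - 1.9999
    - 0.4058
    - -3.9078
  - - 1.7633
    - -0.1908
    - -2.8574
- kind: beta_turn
  cluster_id: 2
  source: turn_II:0
  torsions:
  - - .nan
    - -17.1915
    - 180.0
  - - -64.9292
    - 116.072
    - -180.0
  - - 74.295
    - 4.0695
    - -180.0
  - - -120.4044
    - 125.5264
    - 180.0
  coords:
  - - -1.458
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 0.0
  - - 0.5515
    - 1.4218
    - 0.0
  - - 1.7212
    - 1.6442
    - 0.3125
  - - -0.2984
    - 2.3808
    - -0.3524
  - - 0.1019
    - 3.7821
    - -0.3938
  - - 0.4535
    - 4.2965
    - 0.9982
  - - -0.3999
    - 4.3528
    - 1.8835
  - - 1.7151
    - 4.6707
    - 1.1841
  - - 2.1817
    - 5.1808
    - 2.4678
  - - 2.3248
    - 4.0571
    - 3.4887
  - - 2.6365
    - 4.3005
    - 4.6545
  - - 2.0951
    - 2.8264
    - 3.0428
  - - 2.198
    - 1.6634
    - 3.9161
  - - 3.2446
    - 0.6797
    - 3.4035
  - - 3.1901
    - 0.2438
    - 2.2536
- kind: beta_turn
  cluster_id: 3
  source: turn_IIp:0
  torsions:
  - - .nan
    - -119.2604
    - -180.0
  - - 65.2921
    - -121.9118
    - -180.0
  - - -80.768
    - -2.2282
    - 180.0
  - - -117.0419
    - 124.4802
    - 180.0
  coords:
  - - -1.458
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 0.0
  - - 0.5515
    - 1.4218
    - 0.0
  - - 0.2976
    - 2.1964
    - 0.9225
  - - 1.3071
    - 1.7581
    - -1.0403
  - - 1.8956
    - 3.0864
    - -1.1622
  - - 2.9198
    - 3.3391
    - -0.0609
  - - 3.8935
    - 2.5985
    - 0.0763
  - - 2.6931
    - 4.3892
    - 0.7214
  - - 3.5951
    - 4.7413
    - 1.8115
  - - 3.3291
    - 3.8857
    - 3.0455
  - - 4.0188
    - 4.0078
    - 4.0578
  - - 2.325
    - 3.0199
    - 2.954
  - - 1.9662
    - 2.1427
    - 4.0619
  - - 2.1533
    - 0.6763
    - 3.6873
  - - 1.5958
    - 0.2026
    - 2.6973
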