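# Calibrated kinetic parameters for the synthetic ZWD scenario.
# Generated by scripts/calibrate_zwd.py from data/zwd_anchors.yaml;
# amounts are concentration units (intensity / response_factor).
grid_note: rates per minute, amounts in concentration units
compounds:
  hypaconitine:
    species: A
    ref_time_min: peak
    single:
      M0: 435.1474081933202
      k_d: 0.07339887134136223
      k1: 0.004019588666704659
      k2: 0.0
      f0: 0.15
    co:
      M0: 511.33900798134465
      k_d: 0.0282815497133171
      k1: 0.01981334340489254
      k2: 0.0
      f0: 0.15
    co_modifiers:
      M0: 1.1750937690387788
      k_d: 0.38531314169376996
      k1: 4.9291967531433825
      k2: null
  benzoylhypaconitine:
    species: B
    ref_time_min: 50
    single:
      M0: 1275.630476436768
      k_d: 0.1
      k1: 0.06061083000727735
      k2: 0.007667549929156347
      f0: 0.15
    co:
      M0: 962.6235117228367
      k_d: 0.3229037154842396
      k1: 0.020661231785505947
      k2: 0.0023205698541717483
      f0: 0.15
    co_modifiers:
      M0: 0.7546256768744998
      k_d: 3.2290371548423957
      k1: 0.3408834985929943
      k2: 0.302648156922674
  benzoylmesaconine:
    species: B
    ref_time_min: 50
    single:
      M0: 2216.95032969515
      k_d: 0.1
      k1: 0.08126987087172487
      k2: 0.01260511180079282
      f0: 0.15
    co:
      M0: 1011.0795668059247
      k_d: 0.1257343665220622
      k1: 0.07945641391369947
      k2: 0.0017003281731897309
      f0: 0.15
    co_modifiers:
      M0: 0.45606775815539224
      k_d: 1.257343665220622
      k1: 0.9776859869644959
      k2: 0.13489195495138614
  benzoylaconitine:
    species: B
    ref_time_min: 50
    single:
      M0: 1417.0790537441433
      k_d: 0.1
      k1: 0.06808774312018412
      k2: 0.009525025269253773
      f0: 0.15
    co:
      M0: 696.4385543541187
      k_d: 0.4793444416044694
      k1: 0.0644573732232712
      k2: 0.0008136449878496421
      f0: 0.15
    co_modifiers:
      M0: 0.4914606228311819
      k_d: 4.793444416044694
      k1: 0.9466810070278755
      k2: 0.08542181934950249
  mesaconine:
    species: C
    ref_time_min: 30
    single:
      M0: 1524.5969998208625
      k_d: 0.1
      k1: 0.08
      k2: 0.013423798015776244
      f0: 0.15
      C0: 1.0000000000000013
    co:
      M0: 1010.5968945028355
      k_d: 0.1
      k1: 0.08
      k2: 0.013659718366608432
      f0: 0.15
      C0: 69.14072287587975
    co_modifiers:
      M0: 0.6628616576194095
      k_d: 1.0
      k1: 1.0
      k2: 1.017574784018273
  hypaconine:
    species: C
    ref_time_min: 30
    single:
      M0: 2087.492688715447
      k_d: 0.1
      k1: 0.08
      k2: 0.013555386397544332
      f0: 0.15
      C0: 174.5677525230801
    co:
      M0: 1551.9696001333502
      k_d: 0.1
      k1: 0.08
      k2: 0.012993751020034151
      f0: 0.15
      C0: 261.1885249930084
    co_modifiers:
      M0: 0.743461094988728
      k_d: 1.0
      k1: 1.0
      k2: 0.9585673649545007
  aconine:
    species: C
    ref_time_min: 30
    single:
      M0: 2296.3272414530893
      k_d: 0.1
      k1: 0.08
      k2: 0.013329549761589935
      f0: 0.15
      C0: 268.9138068726528
    co:
      M0: 2901.700270489042
      k_d: 0.1
      k1: 0.08
      k2: 0.020493961454113432
      f0: 0.15
      C0: 4.000000000031589
    co_transient_loss:
    - 0.05
    - 50.0
    - 100.0
    co_modifiers:
      M0: 1.2636266374007215
      k_d: 1.0
      k1: 1.0
      k2: 1.5374833974639015
  pentagalloylglucose:
    species: B
    ref_time_min: 100
    single:
      M0: 2179.847260750053
      k_d: 0.0795919370178134
      k1: 0.0795919370178134
      k2: 0.01583675760815181
      f0: 0.0
    co:
      M0: 2179.847260750053
      k_d: 0.0795919370178134
      k1: 0.0795919370178134
      k2: 0.01583675760815181
      f0: 0.0
    co_modifiers:
      M0: 1.0
      k_d: 1.0
      k1: 1.0
      k2: 1.0
    source_stages: 12
  gallic_acid:
    species: C
    ref_time_min: 0
    single:
      M0: 1041.4351822916653
      k_d: 0.03
      k1: 0.012
      k2: 0.012
      f0: 0.0
      C0: 30.0
    co:
      M0: 266.0809669041892
      k_d: 0.03
      k1: 0.012
      k2: 0.012
      f0: 0.0
      C0: 30.0
    co_modifiers:
      M0: 0.2554945054945055
      k_d: 1.0
      k1: 1.0
      k2: 1.0
  ellagic_acid:
    species: C
    ref_time_min: 0
    single:
      M0: 1137.2815520904862
      k_d: 0.03
      k1: 0.012
      k2: 0.012
      f0: 0.0
      C0: 20.0
    co:
      M0: 270.3725954026439
      k_d: 0.03
      k1: 0.012
      k2: 0.012
      f0: 0.0
      C0: 20.0
    co_modifiers:
      M0: 0.23773584905660378
      k_d: 1.0
      k1: 1.0
      k2: 1.0
  shogaol_6:
    species: B
    ref_time_min: 0
    single:
      M0: 763.8382624124811
      k_d: 0.1
      k1: 0.01
      k2: 0.0
      f0: 0.15
      B0: 342.0
    co:
      M0: 195.4004857334254
      k_d: 0.1
      k1: 0.01
      k2: 0.0
      f0: 0.15
      B0: 342.0
    co_modifiers:
      M0: 0.2558139534883721
      k_d: 1.0
      k1: 1.0
      k2: null
      B0: 1.0
  zingerone:
    species: B
    ref_time_min: 0
    single:
      M0: 1070.2617514035346
      k_d: 0.1
      k1: 0.01
      k2: 0.0
      f0: 0.15
      B0: 166.0
    co:
      M0: 272.5614729974769
      k_d: 0.1
      k1: 0.01
      k2: 0.0
      f0: 0.15
      B0: 93.5
    co_modifiers:
      M0: 0.2546680497925311
      k_d: 1.0
      k1: 1.0
      k2: null
      B0: 0.5632530120481928
  songorine:
    species: A
    ref_time_min: 50
    single:
      M0: 800.0000000002112
      k_d: 0.12
      k1: 0.0
      k2: 0.0
      f0: 0.15
    co:
      M0: 800.0000000002112
      k_d: 0.12
      k1: 0.0
      k2: 0.0
      f0: 0.15
    co_modifiers:
      M0: 1.0
      k_d: 1.0
      k1: null
      k2: null
  atractylenolide_1:
    species: A
    ref_time_min: 50
    single:
      M0: 1200.0000000000002
      k_d: 0.15
      k1: 0.0
      k2: 0.0
      f0: 0.15
    co:
      M0: 1200.0000000000002
      k_d: 0.15
      k1: 0.0
      k2: 0.0
      f0: 0.15
    co_modifiers:
      M0: 1.0
      k_d: 1.0
      k1: null
      k2: null
  paeoniflorin:
    species: A
    ref_time_min: 50
    single:
      M0: 750.0000000240666
      k_d: 0.1
      k1: 0.0
      k2: 0.0
      f0: 0.15
    co:
      M0: 879.4144899343145
      k_d: 0.1
      k1: 0.0036847126693639303
      k2: 0.0
      f0: 0.15
    co_modifiers:
      M0: 1.172552653208127
      k_d: 1.0
      k1: null
      k2: null
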