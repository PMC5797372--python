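surrogate:
  adas_scale: 32.73228805335759
  adas_mid: -87.65557345950513
  w_syn: 0.09936130568004946
  w_neu: 0.5797054780901506
  w_chol: 0.16334534706450896
  ad_offset: -55.207228046225936
  g_mci: 39.9999990655922
  a7_max: 32.781441277811425
  a7_half: 0.020000000000000004
  a7_half_slow: 0.10072689311773898
  a7_frac_fast: 0.9999999999999999
  mci_gain_frac: 0.10000000000000002
  a7_burden: 1.5620246705570624e-34
  burden_sat: 20.000000000000004
  lost_stim_weight: 0.20879809163318508
  attn_load_half: 4.000000000000001
  benefit_cap: 4.5
  acc_scale: 16.999999999999297
  acc_mid: -39.00000000256478
  glu_profile:
  - 3.2118490775283326
  - 4.457634638925852
  - 5.3095451976001495
  - 4.322793401947641
  - 5.480467925158056
receptor:
  gamma: 1.4963768601651453e-11
  w_m1: 0.14322387749297558
  w_gaba: 1.6357932468567902e-05
provenance:
  surrogate_anchors:
  - name: healthy_adas
    target: 4.5
    value: 4.500077424130993
    tol: 0.3
  - name: mci_zero_adas
    target: 4.1
    value: 4.145492021619454
    tol: 0.1
  - name: mci_neg_mean
    target: 7.4
    value: 7.232406445218803
    tol: 1.0
  - name: mci_pos_mean
    target: 10.4
    value: 10.1655609358816
    tol: 1.0
  - name: mci_neg_mean_delta0
    target: 8.4
    value: 7.733650180707026
    tol: 1.5
  - name: mci_pos_mean_delta0
    target: 13.0
    value: 12.702603120565119
    tol: 1.2
  - name: mci_neg_mean_final
    target: 7.8
    value: 7.620890725141679
    tol: 1.2
  - name: mci_pos_mean_final
    target: 11.35
    value: 11.653289644998003
    tol: 0.5
  - name: c1_final_neg_margin
    target: 7.6
    value: 7.620890725141679
    tol: 0.15
  - name: c1_final_pos_margin
    target: 11.6
    value: 11.653289644998003
    tol: 0.15
  - name: ad_baseline_mm
    target: 20.2
    value: 20.20008440806636
    tol: 0.8
  - name: ad_baseline_het
    target: 21.0
    value: 21.083632701270403
    tol: 0.8
  - name: ad_baseline_pp
    target: 22.0
    value: 21.988763297054483
    tol: 0.8
  - name: apoe_week0_gap
    target: 1.8
    value: 1.788678888988123
    tol: 0.25
  - name: placebo_worsening_78
    target: 9.25
    value: 9.275107967039997
    tol: 0.75
  - name: placebo_worsening_78_low
    target: 8.5
    value: 9.827242790712607
    tol: 1.5
  - name: placebo_worsening_78_high
    target: 10.0
    value: 8.475926479689011
    tol: 1.7
  - name: apoe_spread_final
    target: 0.078
    value: 0.09295170757924048
    tol: 0.032
  - name: apoe_spread_delta0
    target: 0.1
    value: 0.02232961733444139
    tol: 0.05
  - name: bace_contrast_low_base
    target: -1.5
    value: -1.4950716467951501
    tol: 0.6
  - name: glu_slope_0
    target: 0.525
    value: 0.508410543876181
    tol: 0.12
  - name: glu_slope_12
    target: 0.65
    value: 0.5892043803825686
    tol: 0.1
  - name: glu_slope_26
    target: 0.65
    value: 0.6015963848433614
    tol: 0.1
  - name: glu_slope_52
    target: 0.4
    value: 0.376292551155899
    tol: 0.1
  - name: glu_slope_78
    target: 0.4
    value: 0.3947097297007929
    tol: 0.1
  receptor_fit:
    slopes_with_benefit:
      Abeta-: -1.1366980161989901
      Abeta+: -1.3675818810661802
    slopes_delta0:
      Abeta-: -1.2447574137698458
      Abeta+: -1.0389269500529554
    baseline_accuracy: 77.38480920467661
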