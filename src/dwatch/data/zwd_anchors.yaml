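# Reference intensity anchors defining the decoction conditions the
# synthetic Zhenwu Decoction (ZWD) scenario emulates.  Intensities are
# detector counts (response_factor x concentration); times are minutes from
# heating onset.  `percent_changes` and `ratios` are the worked summary
# numbers the scenario is calibrated to reproduce; `convention` records
# which reference value each percent change is taken from.
#
# These values are treated as fitted-curve values (not single raw scans).

percent_changes:
  hypaconitine_single:
    reference: 7.36e+3
    final: 3.48e+3
    printed: -52.7
    decimals: 1
    convention: peak_to_end
  benzoylhypaconitine_single:
    reference: 3.66e+4
    final: 9.93e+3
    printed: -72.9
    decimals: 1
    convention: post_dissolution_to_end
  benzoylhypaconitine_co:
    reference: 2.27e+4
    final: 2.45e+4
    printed: 7.9
    decimals: 1
    convention: post_dissolution_to_end
  benzoylmesaconine_single:
    reference: 2.84e+5
    final: 2.86e+4
    printed: -89.9
    decimals: 1
    convention: post_dissolution_to_end
  benzoylmesaconine_co:
    reference: 1.83e+5
    final: 1.39e+5
    printed: -24.0
    decimals: 1
    convention: post_dissolution_to_end
  benzoylaconitine_single:
    reference: 3.92e+4
    final: 7.30e+3
    printed: -81.4
    decimals: 1
    convention: post_dissolution_to_end
  benzoylaconitine_co:
    reference: 2.58e+4
    final: 2.33e+4
    printed: -9.7
    decimals: 1
    convention: post_dissolution_to_end
  mesaconine_single:
    reference: 2.18e+4
    final: 1.46e+5
    printed: 570
    decimals: 0
    convention: t30_to_peak
  shogaol_6_single:
    reference: 3.42e+3
    final: 1.03e+4
    printed: 201.2
    decimals: 1
    convention: start_to_end
  zingerone_single:
    reference: 3.32e+3
    final: 2.26e+4
    printed: 580.7
    decimals: 1
    convention: start_to_end
  zingerone_co:
    reference: 1.87e+3
    final: 6.78e+3
    printed: 262.6
    decimals: 1
    convention: start_to_end

ratios:
  hypaconitine_peak_co_over_single:
    numerator: 4.49e+3
    denominator: 7.36e+3
    printed: 0.61
    decimals: 2
  zingerone_rate_single_over_co:
    numerator: 580.7
    denominator: 262.6
    printed: 2.2
    decimals: 1

# Point anchors used by the generator calibration (5% tolerance).
# t: null means "curve peak, time free".
curve_anchors:
  hypaconitine:
    single:
      - {t: null, v: 7.36e+3, kind: peak}
      - {t: 240, v: 3.48e+3}
    co:
      - {t: null, v: 4.49e+3, kind: peak}
  benzoylhypaconitine:
    single:
      - {t: 50, v: 3.66e+4}
      - {t: 240, v: 9.93e+3}
    co:
      - {t: 50, v: 2.27e+4}
      - {t: 240, v: 2.45e+4}
  benzoylmesaconine:
    single:
      - {t: 50, v: 2.84e+5}
      - {t: 240, v: 2.86e+4}
    co:
      - {t: 50, v: 1.83e+5}
      - {t: 240, v: 1.39e+5}
  benzoylaconitine:
    single:
      - {t: 50, v: 3.92e+4}
      - {t: 240, v: 7.30e+3}
    co:
      - {t: 50, v: 2.58e+4}
      - {t: 240, v: 2.33e+4}
  mesaconine:
    single:
      - {t: 30, v: 2.18e+4}
      - {t: 230, v: 1.46e+5}
    co:
      - {t: 30, v: 2.18e+4}
      - {t: 230, v: 1.02e+5}
  hypaconine:
    single:
      - {t: 30, v: 1.20e+4}
      - {t: 230, v: 5.34e+4}
    co:
      - {t: 30, v: 1.20e+4}
      - {t: 230, v: 4.27e+4}
  aconine:
    single:
      - {t: 30, v: 1.50e+4}
      - {t: 230, v: 6.05e+4}
    co:
      - {t: 30, v: 1.50e+4}
      - {t: 230, v: 2.50e+4}
  songorine:
    single:
      - {t: 240, v: 8.00e+3}
    co:
      - {t: 240, v: 8.00e+3}
  paeoniflorin:
    single:
      - {t: 240, v: 7.50e+4}
    co:
      - {t: 50, v: 7.50e+4}
      - {t: 240, v: 3.75e+4}
  pentagalloylglucose:
    single:
      - {t: 100, v: 1.92e+3}
      - {t: 180, v: 8.62e+3}
      - {t: 225, v: 6.80e+3}
    co:
      - {t: 100, v: 1.92e+3}
      - {t: 180, v: 8.62e+3}
      - {t: 225, v: 6.80e+3}
  gallic_acid:
    single:
      - {t: 240, v: 3.79e+4}
    co:
      - {t: 240, v: 1.08e+4}
  ellagic_acid:
    single:
      - {t: 240, v: 8.15e+3}
    co:
      - {t: 240, v: 2.09e+3}
  shogaol_6:
    single:
      - {t: 0, v: 3.42e+3}
      - {t: 240, v: 1.03e+4}
    co:
      - {t: 0, v: 3.42e+3}
      - {t: 240, v: 5.18e+3}
  zingerone:
    single:
      - {t: 0, v: 3.32e+3}
      - {t: 240, v: 2.26e+4}
    co:
      - {t: 0, v: 1.87e+3}
      - {t: 240, v: 6.78e+3}
  atractylenolide_1:
    single:
      - {t: 240, v: 1.20e+4}
    co:
      - {t: 240, v: 1.20e+4}
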