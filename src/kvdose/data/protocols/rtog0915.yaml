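# 48 Gy / 4 fr constraint set (RTOG 0915 arm).
# Values are the clinical table entries; comparators act on unrounded metrics.
name: RTOG0915
fractions: 4
constraints:
  - {structure: PTV, category: C3, metric: PTV_VpctRx, pct_of_rx: 90, limit: 99, unit: "%", comparator: ">"}
  - {structure: Lt Lung, category: C3, metric: V_D_pct, threshold_dose: 20, limit: 10, unit: "%", comparator: "<="}
  - {structure: Lt Lung, category: C1, metric: Dmean, limit: 6, unit: Gy, comparator: "<="}
  - {structure: Rt Lung, category: C3, metric: V_D_pct, threshold_dose: 20, limit: 10, unit: "%", comparator: "<="}
  - {structure: Rt Lung, category: C1, metric: Dmean, limit: 6, unit: Gy, comparator: "<="}
  - {structure: Trachea PRV, category: C2, metric: V_D_cc, threshold_dose: 15.6, limit: 4, unit: cc, comparator: "<="}
  - {structure: Trachea PRV, category: C1, metric: Dmax_0p03cc, limit: 34.8, unit: Gy, comparator: "<="}
  - {structure: Esophagus PRV, category: C2, metric: V_D_cc, threshold_dose: 18.8, limit: 5, unit: cc, comparator: "<="}
  - {structure: Esophagus PRV, category: C1, metric: Dmax_0p03cc, limit: 30, unit: Gy, comparator: "<="}
  - {structure: PB Tree, category: C2, metric: V_D_cc, threshold_dose: 15.6, limit: 4, unit: cc, comparator: "<="}
  - {structure: PB Tree, category: C1, metric: Dmax_0p03cc, limit: 34.8, unit: Gy, comparator: "<="}
  - {structure: Heart, category: C2, metric: V_D_cc, threshold_dose: 28, limit: 15, unit: cc, comparator: "<="}
  - {structure: Heart, category: C1, metric: Dmax_0p03cc, limit: 34, unit: Gy, comparator: "<="}
  - {structure: Aorta, category: C2, metric: V_D_cc, threshold_dose: 28, limit: 15, unit: cc, comparator: "<="}
  - {structure: Aorta, category: C1, metric: Dmax_0p03cc, limit: 34, unit: Gy, comparator: "<="}
  - {structure: Spinal Cord PRV, category: C2, metric: V_D_cc, threshold_dose: 20.8, limit: 0.35, unit: cc, comparator: "<="}
  - {structure: Spinal Cord PRV, category: C2, metric: V_D_cc, threshold_dose: 13.6, limit: 1.2, unit: cc, comparator: "<="}
  - {structure: Spinal Cord PRV, category: C1, metric: Dmax_0p03cc, limit: 26, unit: Gy, comparator: "<="}
  - {structure: ChestWall, category: C2, metric: V_D_cc, threshold_dose: 30, limit: 70, unit: cc, comparator: "<="}
  - {structure: Skin, category: C2, metric: V_D_cc, threshold_dose: 33.2, limit: 10, unit: cc, comparator: "<="}
  - {structure: Skin, category: C1, metric: Dmax_0p03cc, limit: 36, unit: Gy, comparator: "<"}
report_only:
  # Bone metrics are not part of the clinical protocol; carried for comparison
  # because bone absorbs kV photons ~4x more than soft tissue.
  - {structure: Bone, category: C2, metric: V_D_cc, threshold_dose: 30, unit: cc}
  - {structure: Bone, category: C1, metric: D2pct, unit: Gy}
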