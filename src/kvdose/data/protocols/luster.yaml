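# 60 Gy / 8 fr constraint set (LUSTER arm).
name: LUSTER
fractions: 8
constraints:
  - {structure: PTV, category: C3, metric: PTV_VpctRx, pct_of_rx: 90, limit: 99, unit: "%", comparator: ">"}
  - {structure: Lt Lung, category: C3, metric: V_D_pct, threshold_dose: 20, limit: 10, unit: "%", comparator: "<="}
  - {structure: Lt Lung, category: C1, metric: Dmean, limit: 6, unit: Gy, comparator: "<="}
  - {structure: Rt Lung, category: C3, metric: V_D_pct, threshold_dose: 20, limit: 10, unit: "%", comparator: "<="}
  - {structure: Rt Lung, category: C1, metric: Dmean, limit: 6, unit: Gy, comparator: "<="}
  - {structure: Trachea PRV, category: C2, metric: V_D_cc, threshold_dose: 60, limit: 5, unit: cc, comparator: "<="}
  - {structure: Trachea PRV, category: C1, metric: Dmax_0p03cc, limit: 64, unit: Gy, comparator: "<="}
  - {structure: Esophagus PRV, category: C2, metric: V_D_cc, threshold_dose: 22, limit: 5, unit: cc, comparator: "<="}
  - {structure: Esophagus PRV, category: C1, metric: Dmax_0p03cc, limit: 40, unit: Gy, comparator: "<="}
  - {structure: PB Tree, category: C2, metric: V_D_cc, threshold_dose: 60, limit: 5, unit: cc, comparator: "<="}
  - {structure: PB Tree, category: C1, metric: Dmax_0p03cc, limit: 64, unit: Gy, comparator: "<="}
  - {structure: Heart, category: C2, metric: V_D_cc, threshold_dose: 60, limit: 10, unit: cc, comparator: "<="}
  - {structure: Heart, category: C1, metric: Dmax_0p03cc, limit: 64, unit: Gy, comparator: "<="}
  - {structure: Aorta, category: C2, metric: V_D_cc, threshold_dose: 60, limit: 10, unit: cc, comparator: "<="}
  - {structure: Aorta, category: C1, metric: Dmax_0p03cc, limit: 64, unit: Gy, comparator: "<="}
  - {structure: Spinal Cord PRV, category: C2, metric: V_D_cc, threshold_dose: 22, limit: 1, unit: cc, comparator: "<="}
  - {structure: Spinal Cord PRV, category: C1, metric: Dmax_0p03cc, limit: 32, unit: Gy, comparator: "<="}
  - {structure: ChestWall, category: C2, metric: V_D_cc, threshold_dose: 30, limit: 70, unit: cc, comparator: "<="}
  - {structure: Skin, category: C2, metric: V_D_cc, threshold_dose: 40, limit: 10, unit: cc, comparator: "<="}
  - {structure: Skin, category: C1, metric: Dmax_0p03cc, limit: 45, unit: Gy, comparator: "<"}
report_only:
  - {structure: Bone, category: C2, metric: V_D_cc, threshold_dose: 30, unit: cc}
  - {structure: Bone, category: C1, metric: D2pct, unit: Gy}
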