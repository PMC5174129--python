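"""Drought-physiology indices and the drought-period classification.

Computes the indices the downstream stages consume: relative water content,
the drought-tolerance coefficient from field grain yields, AOC fold
changes, and the soil-water based assignment of sampling timepoints to
drought periods I (mild), II (severe) and III (re-watering).
"""

from droughtmine import (
    AnalysisConfig, classify_drought_periods, drought_tolerance_coefficient,
    relative_water_content, soil_water_cv,
)

# drought-tolerance coefficient = grain yield under drought / well-watered;
# the two cultivars' field yields give sharply contrasting coefficients
for name, (gy_d, gy_w) in {"susceptible": (1.84, 8.90), "tolerant": (7.89, 10.65)}.items():
    dtc = drought_tolerance_coefficient(gy_d, gy_w)
    print(f"{name:12s} GY_D={gy_d:5.2f}  GY_W={gy_w:5.2f}  tolerance coefficient {dtc:.2f}")

rwc = relative_water_content(fresh=0.9, dry=0.2, saturated=1.0)
print(f"leaf RWC for weights (0.9, 0.2, 1.0): {rwc:.3f}  (1.0 = fully turgid)")

# soil water content (%) per timepoint classifies the drought periods:
# >= 18% mild (I), < 15% severe (II), re-watered timepoints are III
swc = {"A": 19.5, "B": 18.6, "C": 14.0, "D": 13.0, "E": 12.0}
periods = classify_drought_periods(swc, rewatered={"F"}, config=AnalysisConfig())
print("period map:", periods)
print(f"within-field SWC variability (CV) at timepoint A plots: "
      f"{soil_water_cv([19.2, 19.6, 19.8]):.2f}%")
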