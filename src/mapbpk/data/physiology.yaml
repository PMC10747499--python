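# Reference physiology and anthropometrics used to build virtual subjects.
#
# These are shipped, overridable defaults in the style of standard PBPK
# reference compilations: organ masses as fractions of body weight with organ
# densities, blood flows as fractions of cardiac output, sex-specific
# anthropometric distributions for adults, and fractional tissue composition
# (water / neutral lipid / phospholipid) per tissue for the
# tissue-composition partition method.  All values are editable config, not
# measurements produced by this package.
#
# Units: body weight kg, heights cm, cardiac output L/h via
# co = co_allometric_l_h_kg075 * BW^0.75, skin thicknesses µm.

co_allometric_l_h_kg075: 13.2   # cardiac output coefficient, L/h per kg^0.75
hematocrit: 0.45

rat:
  reference_weight_kg: 0.25
  skin_thickness_um: [18.0, 32.0, 2040.0]   # SC, VE, DE
  # organ mass fraction of body weight; 'rest' closes the mass balance
  organ_mass_fractions:
    adipose: 0.076
    bone: 0.050
    brain: 0.0057
    gut: 0.027
    heart: 0.0033
    kidney: 0.0073
    liver: 0.0366
    lung: 0.005
    muscle: 0.404
    skin: 0.190
    spleen: 0.002
    blood: 0.074
  # blood flow as fraction of cardiac output (lung carries the full output)
  flow_fractions:
    adipose: 0.070
    bone: 0.122
    brain: 0.020
    gut: 0.131
    heart: 0.049
    kidney: 0.141
    liver: 0.021
    muscle: 0.278
    skin: 0.058
    spleen: 0.020
    rest: 0.050

human:
  skin_thickness_um: [17.0, 47.0, 2906.0]
  anthropometrics:
    male:
      height_mean_cm: 175.3
      height_sd_cm: 7.1
      bmi_median: 27.5
      bmi_log_sd: 0.17
    female:
      height_mean_cm: 161.3
      height_sd_cm: 6.4
      bmi_median: 27.0
      bmi_log_sd: 0.20
  organ_mass_fractions:
    male:
      adipose: 0.200
      bone: 0.086
      brain: 0.020
      gut: 0.024
      heart: 0.0047
      kidney: 0.0044
      liver: 0.026
      lung: 0.0076
      muscle: 0.400
      skin: 0.0371
      spleen: 0.0026
      blood: 0.076
    female:
      adipose: 0.320
      bone: 0.070
      brain: 0.021
      gut: 0.024
      heart: 0.0045
      kidney: 0.0046
      liver: 0.024
      lung: 0.0073
      muscle: 0.300
      skin: 0.0350
      spleen: 0.0025
      blood: 0.070
  flow_fractions:
    adipose: 0.050
    bone: 0.050
    brain: 0.120
    gut: 0.150
    heart: 0.040
    kidney: 0.190
    liver: 0.065
    muscle: 0.170
    skin: 0.050
    spleen: 0.030
    rest: 0.030

organ_densities_g_ml:
  adipose: 0.92
  bone: 1.85
  blood: 1.06
  default: 1.00

# per-area dermal perfusion of patch-covered skin, mL/h per cm² of patch.
# The dermal blood flow Q_DE is an explicit exception to the cardiac-output
# fractions; this default is a physiological resting dermal perfusion scale
# and is flagged in reports.
dermal_perfusion_ml_h_cm2: 1.0

# fractional tissue composition: [water, neutral lipid, phospholipid]
tissue_composition:
  human:
    adipose: [0.180, 0.790, 0.0020]
    bone: [0.439, 0.074, 0.0011]
    brain: [0.770, 0.051, 0.0565]
    gut: [0.718, 0.0487, 0.0163]
    heart: [0.758, 0.0115, 0.0166]
    kidney: [0.783, 0.0207, 0.0162]
    liver: [0.751, 0.0348, 0.0252]
    lung: [0.811, 0.0030, 0.0090]
    muscle: [0.760, 0.0238, 0.0072]
    skin: [0.718, 0.0284, 0.0111]
    spleen: [0.788, 0.0201, 0.0198]
    rest: [0.760, 0.0238, 0.0072]
    plasma: [0.945, 0.0035, 0.00225]
  rat:
    adipose: [0.120, 0.853, 0.0020]
    bone: [0.446, 0.0273, 0.0027]
    brain: [0.788, 0.0392, 0.0533]
    gut: [0.749, 0.0292, 0.0138]
    heart: [0.779, 0.0140, 0.0118]
    kidney: [0.771, 0.0123, 0.0284]
    liver: [0.705, 0.0138, 0.0303]
    lung: [0.790, 0.0219, 0.0140]
    muscle: [0.756, 0.0100, 0.0090]
    skin: [0.651, 0.0239, 0.0111]
    spleen: [0.771, 0.0077, 0.0136]
    rest: [0.756, 0.0100, 0.0090]
    plasma: [0.960, 0.00147, 0.00083]
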