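# First-visit labs and loading dose for the four packaged clinical courses.
# y0: FT4 (pg/mL) and w0: TRAb (U/mL) at the first clinical visit; z0 is the
# assumed functional thyroid size (mL) of an untreated hyperthyroid gland;
# loading_dose_mg sets the initial serum MMI level x0 = dose / 3 L.
patient_20:
  y0: 25.63
  w0: 7.5
  z0: 30.0
  loading_dose_mg: 30.0
patient_31:
  y0: 26.43
  w0: 1.74
  z0: 30.0
  loading_dose_mg: 20.0
patient_55:
  # first-visit TRAb measured as 6.22 U/mL; 6.2 is the value used to
  # initialise the replayed course
  y0: 27.01
  w0: 6.2
  z0: 30.0
  loading_dose_mg: 20.0
patient_70:
  y0: 35.04
  w0: 8.8
  z0: 30.0
  loading_dose_mg: 30.0
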