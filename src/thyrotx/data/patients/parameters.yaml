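# Per-patient model parameter sets for the four packaged clinical courses.
# k1, k2, ka, k4, k5, k6, k8 are population constants; k3, kd, N, k7, kb are
# patient-specific (k3, N, k7 derived from the first clinical visit, kd and kb
# fitted within their admissible bounds).
patient_20:
  k1: 8.374e-3
  k2: 3.3271
  ka: 0.358068
  k3: 0.085
  kd: 0.067
  k4: 0.099021
  k5: 1.0e+6
  N: 0.250
  k6: 0.001
  k7: 0.26
  kb: 4.95
  k8: 0.035
patient_31:
  k1: 8.374e-3
  k2: 3.3271
  ka: 0.358068
  k3: 0.08975
  kd: 0.07
  k4: 0.099021
  k5: 1.0e+6
  N: 0.058
  k6: 0.001
  k7: 0.061
  kb: 11.8
  k8: 0.035
patient_55:
  k1: 8.374e-3
  k2: 3.3271
  ka: 0.358068
  k3: 0.08992
  kd: 0.081
  k4: 0.099021
  k5: 1.0e+6
  N: 0.207
  k6: 0.001
  k7: 0.22
  kb: 4.09
  k8: 0.035
patient_70:
  k1: 8.374e-3
  k2: 3.3271
  ka: 0.358068
  k3: 0.11784
  kd: 0.075
  k4: 0.099021
  k5: 1.0e+6
  N: 0.293
  k6: 0.001
  k7: 0.308
  kb: 3.15
  k8: 0.035
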