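# Package-wide configuration constants.
#
# xyz_to_lms: Hunt-Pointer-Estevez XYZ -> LMS matrix (D65-normalized), used to
# derive cone excitations for display stimuli specified only by CIE xyY.
xyz_to_lms:
  - [0.4002, 0.7076, -0.0808]
  - [-0.2263, 1.1653, 0.0457]
  - [0.0, 0.0, 0.9182]

# L-cone fundamental scaling so that L+M approximates luminous efficiency.
l_scale: 1.98

# Soft-margin SVM cost parameter (libsvm default).
svm_cost: 1.0

# Imaging analysis defaults.
min_colors: 5
connectivity: 8
max_shift: 3
anchor_color: B
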