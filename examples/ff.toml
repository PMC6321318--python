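# Final polarizable four-site water model (combined molecular dispersion
# coefficients in atomic units; geometry in nm / degrees; charges in e).

[geometry]
r_OH = 0.0962
theta_HOH = 105.4
d_OM = 0.0225

[charges]
q_H = 0.539
q_M = -1.078
q_O = 0.0
q_COS = -8.0

[vdw]
r_vdw = 0.1605
c6_au = 43.44
c8_au = 1201.3

[pol]
alpha_iso = 1.05e-3
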