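# Default conditional-logit utility coefficients for hospital choice
# (published obstetric-patient preference estimates).
# Reference levels: level=Low, urbanization=Metro.
beta_lvh_high: -1.072
beta_urb_city: -0.174
beta_urb_rural: -0.862
beta_num: 0.151
beta_tau: -0.064
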