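{
  "name": "canine-orthotropic-fung-v1",
  "description": "Exponent coefficients of the orthotropic Fung-type strain energy Q = bff*Eff^2 + 2*bfs*Efs^2 + 2*bfn*Efn^2 + bss*Ess^2 + bnn*Enn^2 + 2*bsn*Esn^2, in the fiber/sheet/normal frame. Canine passive-myocardium set widely used with this law; unitless.",
  "b_ff": 8.0,
  "b_ss": 6.0,
  "b_nn": 3.0,
  "b_fs": 12.0,
  "b_fn": 3.0,
  "b_sn": 3.0
}
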