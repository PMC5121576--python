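{
  "rabbit_mean": 0.01811667,
  "friedenwald": 0.0215,
  "pallikaris": 0.0126,
  "dastiridou_mean": 0.0224,
  "dastiridou_max": 0.0343
}
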