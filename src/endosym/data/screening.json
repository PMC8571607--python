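{
  "n_screened": 390,
  "infected": {
    "Wolbachia": 47,
    "Cardinium": 11,
    "Arsenophonus": 8
  },
  "coinfections": [
    {"symbionts": ["Wolbachia", "Cardinium"], "samples": ["morph0085", "morph0152", "morph0171"]},
    {"symbionts": ["Wolbachia", "Arsenophonus"], "samples": ["morph0294", "morph0329"]},
    {"symbionts": ["Cardinium", "Arsenophonus"], "samples": ["morph0328"]}
  ]
}
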