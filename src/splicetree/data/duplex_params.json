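{
 "u1_tail": "AUACUUACCUGG",
 "init_penalty": 4.09,
 "wobble_stack": -1.0,
 "stacks": {
  "AA/UU": -0.93,
  "UU/AA": -0.93,
  "AU/UA": -1.1,
  "UA/AU": -1.33,
  "CU/GA": -2.08,
  "AG/UC": -2.08,
  "CA/GU": -2.11,
  "UG/AC": -2.11,
  "GU/CA": -2.24,
  "AC/UG": -2.24,
  "GA/CU": -2.35,
  "UC/AG": -2.35,
  "CG/GC": -2.36,
  "GC/CG": -3.42,
  "GG/CC": -3.26,
  "CC/GG": -3.26
 }
}
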