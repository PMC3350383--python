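{
 "feature": "ME3'ss",
 "threshold": 1.39,
 "yes": {
  "class": "cryptic",
  "group": "a",
  "n": 4
 },
 "no": {
  "feature": "SF2/ASF-D",
  "threshold": 10.53,
  "no": {
   "class": "authentic",
   "group": "A",
   "n": 30
  },
  "yes": {
   "feature": "ME5'ss",
   "threshold": 5.58,
   "yes": {
    "feature": "FE",
    "threshold": -2.6,
    "yes": {
     "class": "cryptic",
     "group": "b",
     "n": 5
    },
    "no": {
     "class": "authentic",
     "group": "B",
     "n": 1
    }
   },
   "no": {
    "feature": "FESS-D",
    "threshold": 4.45,
    "yes": {
     "feature": "GC5'ss",
     "threshold": 46.8,
     "yes": {
      "class": "authentic",
      "group": "C",
      "n": 42
     },
     "no": {
      "feature": "SH3'ss",
      "threshold": 0.79,
      "yes": {
       "class": "cryptic",
       "group": "c",
       "n": 2
      },
      "no": {
       "class": "authentic",
       "group": "E",
       "n": 2
      }
     }
    },
    "no": {
     "feature": "SIZE",
     "threshold": 144,
     "yes": {
      "class": "authentic",
      "group": "D",
      "n": 2
     },
     "no": {
      "class": "cryptic",
      "group": "d",
      "n": 4
     }
    }
   }
  }
 }
}
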