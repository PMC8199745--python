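{
 "meta": {
  "seed": 2024,
  "sampling": {
   "0.1": 300,
   "3.1-": 400,
   "4.1": 150,
   "5.1-": 700,
   "5.2-": 200
  },
  "note": "reduced-sampling reference rates for tests/examples"
 },
 "estimates": [
  {
   "state": "0.1",
   "j": 0.0,
   "q": {},
   "n_conformations": 1200,
   "n_juxtaposed": 0,
   "n_ambiguous": 0,
   "se_j": 0.0,
   "se_q": {}
  },
  {
   "state": "3.1-",
   "j": 0.008125,
   "q": {
    "0.1": 1.0
   },
   "n_conformations": 1600,
   "n_juxtaposed": 13,
   "n_ambiguous": 0,
   "se_j": 0.0026938515062081654,
   "se_q": {
    "0.1": 0.0
   }
  },
  {
   "state": "4.1",
   "j": 0.0016666666666666668,
   "q": {
    "0.1": 1.0
   },
   "n_conformations": 600,
   "n_juxtaposed": 1,
   "n_ambiguous": 0,
   "se_j": 0.0016652771985913182,
   "se_q": {
    "0.1": 0.0
   }
  },
  {
   "state": "5.1-",
   "j": 0.0067857142857142855,
   "q": {
    "3.1-": 1.0
   },
   "n_conformations": 2800,
   "n_juxtaposed": 19,
   "n_ambiguous": 0,
   "se_j": 0.00273125068799986,
   "se_q": {
    "3.1-": 0.0
   }
  },
  {
   "state": "5.2-",
   "j": 0.01375,
   "q": {
    "0.1": 0.7272727272727273,
    "3.1-": 0.09090909090909091,
    "5.1-": 0.18181818181818182
   },
   "n_conformations": 800,
   "n_juxtaposed": 11,
   "n_ambiguous": 0,
   "se_j": 0.005915419469488195,
   "se_q": {
    "0.1": 0.13428162652290843,
    "3.1-": 0.08667841720414475,
    "5.1-": 0.11629129983033297
   }
  }
 ]
}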