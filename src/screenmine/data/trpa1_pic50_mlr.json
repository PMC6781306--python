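{
 "terms": [
  [
   "GRAV4",
   0.0004
  ],
  [
   "khs.dO",
   -0.3038
  ],
  [
   "nHBAcc",
   -0.0954
  ],
  [
   "C2SP3",
   0.2523
  ],
  [
   "DPSA3",
   0.0117
  ],
  [
   "khs.ssCH2",
   -0.0944
  ],
  [
   "nAcid",
   -1.1296
  ],
  [
   "khs.ddsN",
   1.2054
  ],
  [
   "C2SP2",
   -0.06
  ],
  [
   "MDEN13",
   -3.2101
  ],
  [
   "C3SP2",
   0.0939
  ]
 ],
 "intercept": 4.2769
}
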