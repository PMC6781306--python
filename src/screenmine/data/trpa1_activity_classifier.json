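{
 "classifiers": [
  {
   "descriptor": "DPSA3",
   "cutoff": 65.36,
   "direction": "above"
  },
  {
   "descriptor": "ECCEN",
   "cutoff": 440.0,
   "direction": "above"
  },
  {
   "descriptor": "SP6",
   "cutoff": 3.67,
   "direction": "above"
  },
  {
   "descriptor": "SPC4",
   "cutoff": 3.98,
   "direction": "above"
  }
 ],
 "vote_threshold": 3
}
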