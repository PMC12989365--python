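{
  "MICA*002": ["MICA*002", "MICA*110"],
  "MICA*009": ["MICA*009", "MICA*049"],
  "MICA*010": ["MICA*010", "MICA*065", "MICA*069"],
  "MICA*027": ["MICA*027", "MICA*048"],
  "MICA*047": ["MICA*047", "MICA*101"]
}
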