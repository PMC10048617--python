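loci:
- name: D3S1358
  dye: Blue
  repeat_bp: 4
  base_bp: 63
  simple_repeat: false
- name: vWA
  dye: Blue
  repeat_bp: 4
  base_bp: 100
  simple_repeat: false
- name: D16S539
  dye: Blue
  repeat_bp: 4
  base_bp: 212
  simple_repeat: true
- name: CSF1PO
  dye: Blue
  repeat_bp: 4
  base_bp: 277
  simple_repeat: true
- name: TPOX
  dye: Blue
  repeat_bp: 4
  base_bp: 309
  simple_repeat: true
- name: D8S1179
  dye: Green
  repeat_bp: 4
  base_bp: 167
  simple_repeat: false
- name: D21S11
  dye: Green
  repeat_bp: 4
  base_bp: 85
  simple_repeat: false
- name: D18S51
  dye: Green
  repeat_bp: 4
  base_bp: 197
  simple_repeat: false
- name: D2S441
  dye: Yellow
  repeat_bp: 4
  base_bp: 128
  simple_repeat: false
- name: D19S433
  dye: Yellow
  repeat_bp: 4
  base_bp: 46
  simple_repeat: false
- name: TH01
  dye: Yellow
  repeat_bp: 4
  base_bp: 145
  simple_repeat: false
- name: FGA
  dye: Yellow
  repeat_bp: 4
  base_bp: 128
  simple_repeat: false
- name: D22S1045
  dye: Red
  repeat_bp: 3
  base_bp: 55
  simple_repeat: false
- name: D5S818
  dye: Red
  repeat_bp: 4
  base_bp: 90
  simple_repeat: true
- name: D13S317
  dye: Red
  repeat_bp: 4
  base_bp: 172
  simple_repeat: true
- name: D7S820
  dye: Red
  repeat_bp: 4
  base_bp: 221
  simple_repeat: true
- name: SE33
  dye: Purple
  repeat_bp: 4
  base_bp: 234
  simple_repeat: false
- name: D10S1248
  dye: Purple
  repeat_bp: 4
  base_bp: 42
  simple_repeat: true
- name: D1S1656
  dye: Purple
  repeat_bp: 4
  base_bp: 115
  simple_repeat: false
- name: D12S391
  dye: Purple
  repeat_bp: 4
  base_bp: 142
  simple_repeat: false
- name: D2S1338
  dye: Purple
  repeat_bp: 4
  base_bp: 220
  simple_repeat: false
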