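s1:
  a: -2.0400e+1
  b: 7.1347e-6
  c: -3.9880e+0
  d: -2.1035e-7
  L: 5.3037e+0
s2:
  a: -1.0952e+1
  b: 5.0372e-6
  c: -2.6919e+0
  d: -2.0857e-7
  e: 9.3467e-10
  f: 4.8253e-12
  L: 3.6903e+0
schema_version: 1
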