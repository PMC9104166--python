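# Updated Hong Kong IAQ objective: CO, RSP and radon limits tightened.
name: scheme2
limits:
  co2: 1000      # ppm
  co: 6.1        # ppm
  rsp: 100       # ug/m3
  no2: 150       # ug/m3
  o3: 120        # ug/m3
  hcho: 100      # ug/m3
  tvoc: 600      # ug/m3
  radon: 167     # Bq/m3
  abc: 1000      # CFU/m3
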