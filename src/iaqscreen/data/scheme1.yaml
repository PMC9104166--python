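# Old Hong Kong IAQ objective: 8-h exposure limits of satisfactory IAQ.
name: scheme1
limits:
  co2: 1000      # ppm
  co: 8.7        # ppm
  rsp: 180       # ug/m3
  no2: 150       # ug/m3
  o3: 120        # ug/m3
  hcho: 100      # ug/m3
  tvoc: 600      # ug/m3
  radon: 200     # Bq/m3
  abc: 1000      # CFU/m3
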