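{
  "generuler-1kb": [10000, 8000, 6000, 5000, 4000, 3500, 3000, 2500, 2000, 1500, 1000, 750, 500, 250],
  "generuler-1kb-plus": [20000, 10000, 7000, 5000, 4000, 3000, 2000, 1500, 1000, 700, 500, 400, 300, 200, 75],
  "lambda-hindiii": [23130, 9416, 6557, 4361, 2322, 2027, 564, 125],
  "lambda-mix-19": [48502, 24508, 20555, 17000, 15258, 13825, 12119, 10171, 8612, 8271, 6223, 5148, 4268, 3530, 2027, 1904, 1584, 1375, 947]
}
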