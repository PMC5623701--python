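{
 "alphabet": "ACDEFGHIKLMNPQRSTVWY",
 "exchangeabilities": [
  [
   0.0,
   56.0,
   81.0,
   105.0,
   15.0,
   179.0,
   27.0,
   36.0,
   35.0,
   30.0,
   54.0,
   54.0,
   194.0,
   57.0,
   58.0,
   378.0,
   475.0,
   298.0,
   9.0,
   11.0
  ],
  [
   56.0,
   0.0,
   10.0,
   5.0,
   78.0,
   59.0,
   69.0,
   17.0,
   7.0,
   23.0,
   31.0,
   34.0,
   14.0,
   9.0,
   113.0,
   223.0,
   42.0,
   62.0,
   115.0,
   209.0
  ],
  [
   81.0,
   10.0,
   0.0,
   767.0,
   4.0,
   130.0,
   112.0,
   11.0,
   26.0,
   7.0,
   15.0,
   528.0,
   15.0,
   49.0,
   16.0,
   59.0,
   38.0,
   31.0,
   4.0,
   46.0
  ],
  [
   105.0,
   5.0,
   767.0,
   0.0,
   5.0,
   119.0,
   26.0,
   12.0,
   181.0,
   9.0,
   18.0,
   58.0,
   18.0,
   323.0,
   29.0,
   30.0,
   32.0,
   45.0,
   10.0,
   7.0
  ],
  [
   15.0,
   78.0,
   4.0,
   5.0,
   0.0,
   5.0,
   40.0,
   89.0,
   4.0,
   248.0,
   43.0,
   10.0,
   17.0,
   4.0,
   5.0,
   92.0,
   12.0,
   62.0,
   53.0,
   536.0
  ],
  [
   179.0,
   59.0,
   130.0,
   119.0,
   5.0,
   0.0,
   23.0,
   6.0,
   27.0,
   6.0,
   14.0,
   81.0,
   24.0,
   26.0,
   137.0,
   201.0,
   33.0,
   47.0,
   55.0,
   8.0
  ],
  [
   27.0,
   69.0,
   112.0,
   26.0,
   40.0,
   23.0,
   0.0,
   16.0,
   45.0,
   56.0,
   33.0,
   391.0,
   115.0,
   597.0,
   328.0,
   73.0,
   46.0,
   11.0,
   8.0,
   573.0
  ],
  [
   36.0,
   17.0,
   11.0,
   12.0,
   89.0,
   6.0,
   16.0,
   0.0,
   21.0,
   229.0,
   479.0,
   47.0,
   10.0,
   9.0,
   22.0,
   40.0,
   245.0,
   961.0,
   9.0,
   32.0
  ],
  [
   35.0,
   7.0,
   26.0,
   181.0,
   4.0,
   27.0,
   45.0,
   21.0,
   0.0,
   14.0,
   65.0,
   263.0,
   21.0,
   292.0,
   646.0,
   47.0,
   103.0,
   14.0,
   10.0,
   8.0
  ],
  [
   30.0,
   23.0,
   7.0,
   9.0,
   248.0,
   6.0,
   56.0,
   229.0,
   14.0,
   0.0,
   388.0,
   12.0,
   102.0,
   72.0,
   38.0,
   59.0,
   25.0,
   180.0,
   52.0,
   24.0
  ],
  [
   54.0,
   31.0,
   15.0,
   18.0,
   43.0,
   14.0,
   33.0,
   479.0,
   65.0,
   388.0,
   0.0,
   30.0,
   16.0,
   43.0,
   44.0,
   29.0,
   226.0,
   323.0,
   24.0,
   18.0
  ],
  [
   54.0,
   34.0,
   528.0,
   58.0,
   10.0,
   81.0,
   391.0,
   47.0,
   263.0,
   12.0,
   30.0,
   0.0,
   15.0,
   86.0,
   45.0,
   503.0,
   232.0,
   16.0,
   8.0,
   70.0
  ],
  [
   194.0,
   14.0,
   15.0,
   18.0,
   17.0,
   24.0,
   115.0,
   10.0,
   21.0,
   102.0,
   16.0,
   15.0,
   0.0,
   164.0,
   74.0,
   285.0,
   118.0,
   23.0,
   6.0,
   10.0
  ],
  [
   57.0,
   9.0,
   49.0,
   323.0,
   4.0,
   26.0,
   597.0,
   9.0,
   292.0,
   72.0,
   43.0,
   86.0,
   164.0,
   0.0,
   310.0,
   53.0,
   51.0,
   20.0,
   18.0,
   24.0
  ],
  [
   58.0,
   113.0,
   16.0,
   29.0,
   5.0,
   137.0,
   328.0,
   22.0,
   646.0,
   38.0,
   44.0,
   45.0,
   74.0,
   310.0,
   0.0,
   101.0,
   64.0,
   17.0,
   126.0,
   20.0
  ],
  [
   378.0,
   223.0,
   59.0,
   30.0,
   92.0,
   201.0,
   73.0,
   40.0,
   47.0,
   59.0,
   29.0,
   503.0,
   285.0,
   53.0,
   101.0,
   0.0,
   477.0,
   38.0,
   35.0,
   63.0
  ],
  [
   475.0,
   42.0,
   38.0,
   32.0,
   12.0,
   33.0,
   46.0,
   245.0,
   103.0,
   25.0,
   226.0,
   232.0,
   118.0,
   51.0,
   64.0,
   477.0,
   0.0,
   112.0,
   12.0,
   21.0
  ],
  [
   298.0,
   62.0,
   31.0,
   45.0,
   62.0,
   47.0,
   11.0,
   961.0,
   14.0,
   180.0,
   323.0,
   16.0,
   23.0,
   20.0,
   17.0,
   38.0,
   112.0,
   0.0,
   25.0,
   16.0
  ],
  [
   9.0,
   115.0,
   4.0,
   10.0,
   53.0,
   55.0,
   8.0,
   9.0,
   10.0,
   52.0,
   24.0,
   8.0,
   6.0,
   18.0,
   126.0,
   35.0,
   12.0,
   25.0,
   0.0,
   71.0
  ],
  [
   11.0,
   209.0,
   46.0,
   7.0,
   536.0,
   8.0,
   573.0,
   32.0,
   8.0,
   24.0,
   18.0,
   70.0,
   10.0,
   24.0,
   20.0,
   63.0,
   21.0,
   16.0,
   71.0,
   0.0
  ]
 ],
 "frequencies": [
  0.076748,
  0.019803,
  0.051544,
  0.06183,
  0.040126,
  0.073152,
  0.022944,
  0.053761,
  0.058676,
  0.091904,
  0.023826,
  0.042645,
  0.050901,
  0.040752,
  0.051691,
  0.068765,
  0.058565,
  0.066005,
  0.014261,
  0.032102
 ]
}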