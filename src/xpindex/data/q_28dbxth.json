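{
 "name": "q_28dbxth",
 "provenance": "Literature-reported correction matrix Q for 2,8-DBXTH and its reported eigenvalue list, transcribed verbatim from the source study's construction worked example. The matrix is non-symmetric as printed and its eigenvalues (general solver) do not match the reported list; shipped as reference data, not as a pipeline output.",
 "q": [
  [
   9.6325,
   6.5987,
   8.3568,
   6.3326,
   7.3587,
   6.9985,
   7.0257,
   8.9859,
   9.0257,
   12.3266,
   10.3658,
   11.3582,
   8.3698,
   7.5628,
   8.6329,
   9.3251,
   10.2122
  ],
  [
   8.3571,
   8.3369,
   11.3201,
   12.3658,
   8.3654,
   10.3222,
   12.011,
   10.2156,
   9.7555,
   12.3655,
   11.0001,
   10.2254,
   9.1248,
   10.2512,
   9.3562,
   9.2356,
   9.62587
  ],
  [
   11.2551,
   10.9952,
   9.9852,
   11.0321,
   9.6657,
   9.9523,
   11.0275,
   11.3214,
   10.2255,
   11.0215,
   10.0189,
   9.8952,
   10.2525,
   9.5986,
   10.2578,
   10.2546,
   10.2658
  ],
  [
   12.0302,
   10.3251,
   10.9958,
   10.2045,
   10.7895,
   11.2546,
   8.3251,
   12.1231,
   11.2126,
   12.2132,
   11.0211,
   9.2012,
   11.0025,
   10.2356,
   11.2456,
   11.3254,
   11.0212
  ],
  [
   8.3265,
   8.0092,
   9.6697,
   10.0012,
   11.2541,
   10.0018,
   9.3259,
   10.3259,
   10.9956,
   11.2258,
   9.2356,
   8.2659,
   10.2152,
   12.321,
   10.2365,
   10.2563,
   10.3254
  ],
  [
   9.2351,
   7.9858,
   10.3258,
   9.8989,
   10.5564,
   10.2129,
   8.9751,
   13.0013,
   12.3568,
   10.3215,
   9.2258,
   9.2012,
   10.2578,
   11.0285,
   12.3546,
   11.3258,
   11.3256
  ],
  [
   10.0332,
   8.0324,
   11.0322,
   10.2253,
   11.2359,
   11.9513,
   10.2175,
   12.3217,
   13.0201,
   9.8652,
   10.2587,
   11.0215,
   11.3219,
   9.5689,
   11.3258,
   12.5263,
   11.0321
  ],
  [
   11.0114,
   9.1225,
   10.2254,
   11.2254,
   11.0003,
   11.0215,
   11.2141,
   12.0008,
   11.9586,
   9.1256,
   11.2035,
   10.2578,
   10.2587,
   9.5268,
   10.2569,
   13.2512,
   10.2658
  ],
  [
   8.3269,
   8.9659,
   11.0002,
   10.3325,
   10.9951,
   9.2568,
   10.2518,
   11.5672,
   11.0245,
   10.2785,
   10.5254,
   11.2515,
   11.0215,
   10.2586,
   10.2987,
   12.0035,
   9.9652
  ],
  [
   9.0059,
   9.0258,
   10.2121,
   10.0001,
   10.2545,
   9.2564,
   11.2152,
   12.3121,
   10.2578,
   11.3271,
   11.0021,
   10.2129,
   12.0006,
   11.2489,
   11.2546,
   11.9658,
   9.9965
  ],
  [
   8.3511,
   10.2587,
   11.0368,
   9.2568,
   9.6875,
   10.3256,
   10.2955,
   10.2125,
   11.2151,
   12.521,
   10.2258,
   12.0321,
   11.0289,
   10.2574,
   10.2548,
   12.2512,
   10.3256
  ],
  [
   8.9778,
   11.3585,
   12.3325,
   10.2254,
   10.0098,
   9.3695,
   11.2121,
   11.2012,
   10.8985,
   11.3215,
   9.5858,
   11.0021,
   10.0098,
   10.2546,
   11.6548,
   11.6958,
   11.3245
  ],
  [
   9.0022,
   12.1123,
   11.0332,
   10.5587,
   11.2541,
   13.3121,
   10.6589,
   11.0259,
   11.3258,
   11.0338,
   10.2515,
   9.9562,
   9.5867,
   10.2354,
   11.2154,
   12.3568,
   11.9658
  ],
  [
   8.9523,
   10.3258,
   8.2257,
   9.9957,
   10.3254,
   10.2356,
   10.5268,
   10.5689,
   11.0208,
   10.2215,
   11.2578,
   12.3251,
   9.1246,
   11.2368,
   12.0221,
   11.9856,
   11.3256
  ],
  [
   7.2258,
   8.9657,
   9.0056,
   8.5987,
   10.0011,
   12.3211,
   11.3211,
   11.2571,
   10.3118,
   11.0002,
   10.2512,
   11.8595,
   9.1978,
   12.3258,
   13.0005,
   12.0036,
   10.2586
  ],
  [
   8.2369,
   8.5662,
   10.3278,
   9.3359,
   10.2125,
   10.2113,
   10.2312,
   12.3215,
   9.5687,
   10.0017,
   11.2589,
   11.0017,
   10.2587,
   10.2587,
   12.6589,
   11.6985,
   11.2351
  ],
  [
   9.3368,
   7.2655,
   8.3365,
   9.0012,
   9.5875,
   10.2103,
   8.2951,
   12.3895,
   9.5235,
   8.9526,
   12.2123,
   9.8945,
   10.2132,
   9.4569,
   11.2548,
   10.2512,
   12.021
  ]
 ],
 "eigenvalues": [
  -9.3541,
  -6.5978,
  -4.5987,
  -2.2512,
  -1.3575,
  -1.03279,
  -0.80915,
  -0.6308,
  5.1485,
  7.9062,
  11.3299,
  16.0541,
  19.1825,
  21.9817,
  22.3654,
  36.3718,
  58.2157
 ]
}
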