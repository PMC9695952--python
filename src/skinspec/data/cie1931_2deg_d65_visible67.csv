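# CIE colorimetry tables on the 67-point visible grid (400-730 nm, 5 nm step).
# xbar/ybar/zbar: CIE 1931 2-degree color-matching functions via the
#   Wyman-Sloan-Shirley multi-lobe Gaussian analytic fit (JCGT 2013).
# d65: CIE standard illuminant D65 relative SPD, 10-nm abridged table
#   linearly interpolated to 5 nm (normalized to 100 at 560 nm).
wavelength_nm,xbar,ybar,zbar,d65
400,0.011674,0.001280,0.060786,82.750
405,0.025189,0.001867,0.109896,87.120
410,0.049306,0.002691,0.205061,91.490
415,0.087562,0.003837,0.378386,92.460
420,0.141073,0.005408,0.654302,93.430
425,0.206194,0.007536,1.016929,90.055
430,0.273393,0.010384,1.386823,86.680
435,0.328801,0.014146,1.644122,95.770
440,0.358601,0.019054,1.733914,104.860
445,0.358492,0.025376,1.776198,110.935
450,0.343750,0.033415,1.781385,117.010
455,0.317285,0.043507,1.746756,117.410
460,0.281210,0.056017,1.671217,117.810
465,0.238333,0.071346,1.518440,116.335
470,0.191832,0.089944,1.294473,114.860
475,0.144969,0.112375,1.044059,115.390
480,0.100877,0.139442,0.809347,115.920
485,0.062410,0.172381,0.614845,112.365
490,0.032012,0.213069,0.465525,108.810
495,0.011584,0.264051,0.354289,109.080
500,0.002355,0.328117,0.270763,109.350
505,0.004352,0.407184,0.206459,108.575
510,0.016480,0.500611,0.155962,107.800
515,0.038427,0.603645,0.116130,106.295
520,0.069841,0.707113,0.084991,104.790
525,0.110357,0.799198,0.061058,106.240
530,0.159607,0.869052,0.043036,107.690
535,0.217189,0.917086,0.029754,106.050
540,0.282597,0.954169,0.020178,104.410
545,0.355116,0.979994,0.013423,104.230
550,0.433715,0.994462,0.008758,104.050
555,0.516945,0.997928,0.005605,102.025
560,0.602888,0.991082,0.003518,100.000
565,0.689144,0.974833,0.002166,98.165
570,0.772903,0.950106,0.001308,96.330
575,0.851072,0.915781,0.000775,96.060
580,0.920461,0.872134,0.000450,95.790
585,0.978012,0.820556,0.000257,92.240
590,1.021039,0.762587,0.000143,88.690
595,1.047451,0.699877,0.000079,89.350
600,1.055926,0.634136,0.000042,90.010
605,1.041185,0.567075,0.000022,89.805
610,1.000205,0.500339,0.000012,89.600
615,0.936095,0.435439,0.000006,88.650
620,0.853537,0.373692,0.000003,87.700
625,0.758222,0.316170,0.000001,85.495
630,0.656211,0.263667,0.000001,83.290
635,0.553302,0.216694,0.000000,83.495
640,0.454521,0.175480,0.000000,83.700
645,0.363763,0.140007,0.000000,81.865
650,0.283632,0.110045,0.000000,80.030
655,0.215459,0.085204,0.000000,80.120
660,0.159458,0.064982,0.000000,80.210
665,0.114974,0.048814,0.000000,81.245
670,0.080766,0.036117,0.000000,82.280
675,0.055275,0.026320,0.000000,80.280
680,0.036855,0.018890,0.000000,78.280
685,0.023941,0.013353,0.000000,74.000
690,0.015152,0.009297,0.000000,69.720
695,0.009342,0.006374,0.000000,70.665
700,0.005612,0.004305,0.000000,71.610
705,0.003284,0.002863,0.000000,72.980
710,0.001873,0.001875,0.000000,74.350
715,0.001040,0.001210,0.000000,67.975
720,0.000563,0.000769,0.000000,61.600
725,0.000297,0.000481,0.000000,65.745
730,0.000152,0.000296,0.000000,69.890
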