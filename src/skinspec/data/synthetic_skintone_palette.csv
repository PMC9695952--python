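# synthetic skin-tone palette (NOT a commercial guide); for tests/demos
id,L,a,b
ST01,75.00,6.23,15.61
ST02,73.45,8.02,15.31
ST03,71.90,9.90,12.61
ST04,70.34,7.48,15.59
ST05,68.79,8.71,15.81
ST06,67.24,9.53,16.70
ST07,65.69,9.83,16.33
ST08,64.14,9.34,15.99
ST09,62.59,9.85,15.79
ST10,61.03,12.32,16.34
ST11,59.48,11.59,17.22
ST12,57.93,10.74,17.25
ST13,56.38,8.44,19.49
ST14,54.83,13.06,16.14
ST15,53.28,13.46,18.42
ST16,51.72,13.61,21.40
ST17,50.17,12.13,21.07
ST18,48.62,13.75,20.68
ST19,47.07,13.49,22.53
ST20,45.52,11.48,22.60
ST21,43.97,12.48,23.60
ST22,42.41,14.51,23.57
ST23,40.86,13.80,23.11
ST24,39.31,15.12,22.53
ST25,37.76,16.09,21.69
ST26,36.21,14.37,22.39
ST27,34.66,15.41,23.47
ST28,33.10,15.19,27.67
ST29,31.55,14.37,26.05
ST30,30.00,15.47,26.14
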