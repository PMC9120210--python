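id,reference_id,pf,ci_low,ci_high,n,location,country,latitude,longitude,living_condition,ratio_type
2,2,0.48,0.41,0.50,203,Diverse,Switzerland,46.95,7.62,F,S
5,5,0.44,0.40,0.48,679,Diverse,Switzerland,46.82,8.63,F,S
9,8,0.47,0.43,0.52,475,Diverse,Sweden,62.39,16.32,F,S
11,9,0.49,0.41,0.57,168,Kaloe,Denmark,56.29,10.48,F,S
12,9,0.43,0.33,0.54,97,Borris,Denmark,55.95,8.66,F,S
20,15,0.43,0.35,0.51,147,Stammham,Germany,48.86,11.46,E,S
29,19,0.50,0.46,0.54,763,Diverse,Austria,48.65,15.39,F,S
52,28,0.51,0.45,0.57,293,Storfosna,Norway,63.67,9.41,FI,S
58,34,0.55,0.46,0.64,134,Caceres,Spain,39.51,-6.26,F,S
59+61,35+37,0.55,0.46,0.63,132,Tredozio,Italy,44.05,11.74,F,S
60,36,0.48,0.45,0.51,1235,Chize,France,46.13,-0.40,FI,S
56+63,32+39,0.47,0.46,0.49,5315,Diverse,Switzerland,46.93,8.45,F,S
87,44,0.49,0.46,0.52,1083,Trois Fontaine,France,48.70,4.93,FI,S
90,47,0.48,0.47,0.49,12473,Diverse,Germany,48.60,9.01,F,S
91,48,0.51,0.44,0.57,223,Niederfinow,Germany,52.85,13.91,E,S
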