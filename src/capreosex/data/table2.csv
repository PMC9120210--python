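id,reference_id,pf,ci_low,ci_high,n,country,living_condition,ratio_type,source
2,2,0.48,0.41,0.55,203,Switzerland,F,S,Kurt and Saegesser 1966
5,5,0.44,0.40,0.48,679,Switzerland,F,S,Kurt 1968
6,6,0.47,0.34,0.61,55,Great Britain,F,P,Prior 1968
8S,8,0.56,0.46,0.65,108,Sweden,F,S,Borg 1971
8P,8,0.47,0.43,0.52,475,Sweden,F,P,Borg 1971
9,9,0.47,0.41,0.53,265,Denmark,F,S,Strangaard 1972
10,10,0.57,0.48,0.66,117,Germany,F,P,Georgii 1973
11,11,0.45,0.36,0.49,262,Switzerland,F,P,Wandeler 1975
15,15,0.47,0.39,0.54,193,Germany,E,S,Ellenberg 1978
16,16,0.56,0.46,0.65,111,Poland,F,P,Fruzinski and Labudski 1982
17,17,0.46,0.40,0.52,298,Poland,F,P,Kaluzinski 1982
18,18,0.48,0.40,0.55,116,Germany,F,P,Stubbe et al. 1982
19,19,0.50,0.46,0.54,763,Austria,F,S,Engl 1982
23,23,0.48,0.45,0.50,1600,Great Britain,F,P,Hewison 1993
24,24,0.49,0.41,0.58,142,Belgium,F,P,Wauters et al. 1995
30,30,0.51,0.45,0.57,293,Norway,FI,S,Linnell and Andersen 1998
34,34,0.55,0.46,0.64,134,Spain,F,S,Quesada and Carranza 2000
35+37,35+37,0.55,0.46,0.63,132,Italy,F,S,Focardi et al. 2002; Pelliccioni et al. 2004
36,36,0.48,0.45,0.51,1235,France,FI,S,Pettorelli et al. 2005
32+39,32+39,0.47,0.46,0.49,5315,Switzerland,F,S,Mueri 1999; Signer and Jenny 2006
40,40,0.60,0.48,0.72,73,Hungary,F,P,Majzinger 2006
42,42,0.47,0.46,0.49,2613,Great Britain,F,P,MacDonald and Johnsen 2008
44,44,0.49,0.46,0.52,1083,France,FI,S,Plard et al. 2014
47,47,0.48,0.47,0.49,12473,Germany,F,S,Baden-Wuerttemberg tagging programme 1972-2019
48,48,0.51,0.44,0.57,223,Germany,E,S,Niederfinow enclosure (S. Ortmann)
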