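time_months,prevalence,denominator
-60.0,0.002074360505452264,23956.0
-57.0,0.0011206666444442785,23956.0
-54.0,0.0,23956.0
-51.0,0.002218789024281718,23956.0
-48.0,0.000805920008823912,23956.0
-45.0,0.0007705764567155805,23956.0
-42.0,0.001236151254916145,23956.0
-39.0,0.00024071419804908706,23956.0
-36.0,0.0011237209548404063,23956.0
-33.0,0.0013805797737455987,23956.0
-30.0,0.0002599131293013167,23956.0
-27.0,0.0004750287523474332,23956.0
-24.0,0.00023096922094372613,23956.0
-21.0,0.00019562566883539814,23956.0
-18.0,0.0028735898475669326,23956.0
-15.0,0.006929079489647948,23956.0
-12.0,0.015117145521777394,23956.0
-9.0,0.03278091701391685,23956.0
-6.0,0.053617171391346,23956.0
-3.0,0.04807172598583977,23956.0
0.0,0.04494738594015989,23956.0
3.0,0.03890102218434477,23956.0
6.0,0.032103280903066286,23956.0
9.0,0.029772061578708823,23956.0
12.0,0.026397262357874495,23956.0
15.0,0.023147692724617395,23956.0
18.0,0.019021515978319716,23956.0
21.0,0.018693970055197854,23956.0
24.0,0.017573303410753572,23956.0
27.0,0.015242084086396119,23956.0
30.0,0.01366224228750201,23956.0
33.0,0.012416346055480507,23956.0
36.0,0.01029384271041842,23956.0
39.0,0.00858877132394709,23956.0
42.0,0.009680494060033792,23956.0
45.0,0.0061804652516222365,23956.0
48.0,0.00622860809123205,23956.0
51.0,0.0064019805184190905,23956.0
54.0,0.004112504389920713,23956.0
57.0,0.004244133621248678,23956.0
60.0,0.005043653986321842,23956.0
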