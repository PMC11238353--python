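participant,baseline_f1,second_opinion_mean,second_opinion_sd,majority_mean,majority_sd
1,0.476,0.608,0.021,0.579,0.024
2,0.491,0.634,0.024,0.600,0.025
3,0.519,0.576,0.020,0.545,0.024
4,0.546,0.590,0.020,0.560,0.025
5,0.549,0.672,0.019,0.615,0.024
6,0.562,0.605,0.027,0.565,0.026
7,0.565,0.611,0.022,0.569,0.024
8,0.572,0.663,0.020,0.611,0.025
9,0.576,0.646,0.022,0.615,0.025
10,0.580,0.623,0.022,0.612,0.025
11,0.581,0.626,0.019,0.607,0.022
12,0.584,0.649,0.022,0.615,0.023
13,0.592,0.632,0.021,0.607,0.022
14,0.593,0.669,0.024,0.630,0.024
15,0.597,0.659,0.023,0.612,0.025
16,0.603,0.642,0.028,0.615,0.028
17,0.603,0.649,0.020,0.620,0.024
18,0.613,0.644,0.020,0.598,0.023
19,0.615,0.683,0.021,0.620,0.023
20,0.615,0.640,0.022,0.596,0.023
21,0.632,0.658,0.023,0.603,0.024
22,0.635,0.702,0.018,0.650,0.023
23,0.637,0.665,0.026,0.648,0.026
24,0.653,0.693,0.019,0.643,0.026
25,0.670,0.686,0.020,0.659,0.026
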