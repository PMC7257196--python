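item,detrending,family1,family2,nugget,psill1,psill2,range1,range2,rmspe,pct_rmspe_change,anisotropy
Garbage,3rd order spatial,sine_hole,matern,0.935,0.063,0.13,4.731,0.871,0.3940,,None
Garbage,3rd order spatial + rater,sine_hole,matern,0.727,0.063,0.104,4.385,0.795,0.3376,-14.31,None
Abandoned cars,3rd order spatial,sine_hole,sine_hole,0,0.012,0.007,1e-6,1e-6,0.0491,,NA
Abandoned cars,3rd order spatial + rater,spherical,sine_hole,6.80e-4,0.16,0.002,1e-6,0.762,0.0489,-0.32,NA
Building conditions ≥ moderate,3rd order spatial,power,sine_hole,0.532,1e-6,0.0247,0.513,2.470,0.2806,,≥ Mid-range
Building conditions ≥ moderate,3rd order spatial + rater,sine_hole,sine_hole,4.70e-6,0.025,0.493,2.489,1e-6,0.2704,-3.63,≥ Mid-range
Yard conditions ≥ moderate,3rd order spatial,sine_hole,matern,0.459,0.045,0.019,2.614,1e-6,0.2596,,≥ Mid-range
Yard conditions ≥ moderate,3rd order spatial + rater,power,sine_hole,0.429,1.4e-6,0.045,0,2.655,0.2455,-5.44,≥ Mid-range
Dumpster,3rd order spatial,matern,sine_hole,0.501,1.0e-6,0.007,9.052,1.650,0.2596,,≥ Mid-range
Dumpster,3rd order spatial + rater,sine_hole,sine_hole,0.485,0.015,1.0e-6,0.821,6.511,0.2567,-1.11,≥ Mid-range
Graffiti,3rd order spatial,sine_hole,gaussian,0.025,0.017,0.421,1.020,1.0e-6,0.2606,,≥ Mid-range
Graffiti,3rd order spatial + rater,matern,sine_hole,0.433,6.3e-5,0.016,10.141,1.028,0.2566,-1.54,≥ Mid-range
Boarded/burned building,3rd order spatial,cubic,,0.032,0.306,,0.231,,0.2138,,≥ Mid-range
Boarded/burned building,3rd order spatial + rater,spherical,matern,0.004,1.0e-6,0.333,4.085,0.094,0.2140,0.12,≥ Mid-range
Outdoor seating,3rd order spatial,sine_hole,,1.131,0.015,,4.405,,0.4222,,None
Outdoor seating,3rd order spatial + rater,sine_hole,spherical,0.006,0.011,1.089,4.385,1.0e-6,0.4078,-3.41,None
Team sports,3rd order spatial,power,sine_hole,0.1658,8.6e-5,0.023,2,6.4e-5,0.1352,,None
Team sports,3rd order spatial + rater,power,,0.186,8.70e-5,,2,,0.1349,-0.22,None
Yard decorations,3rd order spatial,sine_hole,gaussian,1.095,0.046,0.146,4.591,0.649,0.4208,,None
Yard decorations,3rd order spatial + rater,sine_hole,matern,0.023,0.048,1.141,4.652,0.278,0.4003,-4.87,None
Fences,3rd order spatial,gaussian,exponential,0.65,0.109,0.200,10.758,0.435,0.3443,,≥ Mid-range
Fences,3rd order spatial + rater,sine_hole,matern,4.10e-5,0.064,0.826,10.723,0.351,0.3311,-3.81,≥ Mid-range
Sidewalk present,3rd order spatial,matern,sine_hole,0,0.904,0.069,1.869,3.022,0.2952,,≥ Mid-range
Sidewalk present,3rd order spatial + rater,power,matern,0.558,2.70e-4,0.381,2,1.683,0.3035,2.8,≥ Mid-range
Complete sidewalk,3rd order spatial,gaussian,sine_hole,0.443,0.164,0.015,7.648,2.542,0.2512,,None
Complete sidewalk,3rd order spatial + rater,gaussian,spherical,0.432,0.107,0.070,8.959,10.3981,0.2511,-0.01,None
Sidewalk condition,3rd order spatial,gaussian,sine_hole,1.225,1.8e-6,0.029,1.0e-6,2.409,0.4403,,None
Sidewalk condition,3rd order spatial + rater,exponential,sine_hole,1.106,1.0e-6,0.034,4.139,2.495,0.4297,-2.39,None
Sidewalk width,3rd order spatial,gaussian,exponential,0.019,0.637,0.005,0.099,1.0e-6,0.2870,,None
Sidewalk width,3rd order spatial + rater,cubic,matern,0.11,1.0e-6,0.538,4.782,0.109,0.2779,-3.18,None
Sidewalk from curb distance,3rd order spatial,sine_hole,spherical,0.04,0.076,0.011,1.0e-6,3.918,0.0938,,≥ Mid-range
Sidewalk from curb distance,3rd order spatial + rater,sine_hole,exponential,0.036,0.012,0.076,3.953,1.0e-6,0.0936,-0.15,≥ Mid-range
Car obstruction,3rd order spatial,gaussian,cubic,0.09,9.5e-4,0.320,1.0e-6,0.251,0.2003,,≥ Mid-range
Car obstruction,3rd order spatial + rater,spherical,spherical,0.006,0.368,0.034,0.208,1.0e-6,0.1996,-0.32,≥ Mid-range
Garbage can obstruction,3rd order spatial,power,,0.388,1.60e-4,,2,,0.1979,,None
Garbage can obstruction,3rd order spatial + rater,power,sine_hole,0.372,1.4e-4,0.014,2,1.0e-6,0.1974,-0.27,None
Pole or sign obstruction,3rd order spatial,power,,0.338,5.90e-4,,2,,0.1620,,≥ Mid-range
Pole or sign obstruction,3rd order spatial + rater,power,sine_hole,0.018,6.2e-5,0.298,2,1.0e-6,0.1624,0.29,≥ Mid-range
Other obstruction,3rd order spatial,spherical,gaussian,6.10e-4,2.2e-4,0.495,1.0e-6,0.067,0.2450,,None
Other obstruction,3rd order spatial + rater,matern,matern,2.80e-4,1.6e-4,0.491,1.0e-6,0.068,0.2427,-0.93,None
Curb cuts,3rd order spatial,matern,sine_hole,9.00e-9,1.345,0.026,0.094,4.131,0.4751,,None
Curb cuts,3rd order spatial + rater,sine_hole,power,1.186,6.1e-3,0.030,4.303,0.360,0.4587,-3.45,None
Clear intersection,3rd order spatial,sine_hole,matern,3.30e-5,0.028,1.272,12.078,0.409,0.4148,,None
Clear intersection,3rd order spatial + rater,sine_hole,matern,9.20e-5,0.028,1.271,11.815,0.410,0.4143,-0.12,None
Pedestrian crossing sign,3rd order spatial,spherical,cubic,0.383,1.0e-6,0.494,6.008,0.258,0.3739,,None
Pedestrian crossing sign,3rd order spatial + rater,spherical,matern,0.242,1.0e-3,0.630,1.0e-6,8.550,0.3747,0.2,None
Pedestrian signal,3rd order spatial,spherical,matern,0.063,6.8e-4,0.713,1.0e-6,0.148,0.3348,,≥ Mid-range
Pedestrian signal,3rd order spatial + rater,matern,matern,0.117,4.5e-3,0.646,8.045,0.1523,0.3326,-0.67,≥ Mid-range
Pedestrian crossing marks,3rd order spatial,sine_hole,matern,0.649,0.074,0.416,8.039,0.991,0.3634,,≥ Mid-range
Pedestrian crossing marks,3rd order spatial + rater,sine_hole,matern,0.597,0.068,0.447,7.660,0.988,0.3676,1.15,≥ Mid-range
Type of pedestrian crosswalk marks,3rd order spatial,sine_hole,gaussian,0.669,0.053,0.457,3.671,0.259,0.3582,,"Yes, E-SE"
Type of pedestrian crosswalk marks,3rd order spatial + rater,sine_hole,matern,0,0.052,1.124,3.672,0.187,0.3530,-1.44,"Yes, E-SE"
Traffic signal type,3rd order spatial,sine_hole,cubic,0.8,0.119,0.215,11.930,0.631,0.3786,,None
Traffic signal type,3rd order spatial + rater,matern,spherical,0.779,0.174,0.226,11.967,0.583,0.3763,-0.59,None
One-way street,3rd order spatial,exponential,matern,0.081,1.0e-6,0.462,6.700,0.146,0.2397,,≥ Mid-range
One-way street,3rd order spatial + rater,sine_hole,exponential,0.005,0.041,0.491,0.182,0.100,0.2412,0.62,≥ Mid-range
Number of lanes,3rd order spatial,exponential,sine_hole,0.493,0.188,0.057,0.690,2.295,0.3066,,≥ Mid-range
Number of lanes,3rd order spatial + rater,matern,spherical,0.22,0.364,0.155,0.210,3.020,0.2880,-6.09,≥ Mid-range
Presence of highway,3rd order spatial,power,matern,0.126,1.9e-4,0.236,2,0.738,0.1611,,≥ Mid-range
Presence of highway,3rd order spatial + rater,power,matern,0.126,1.9e-4,0.236,2,0.737,0.1616,0.31,≥ Mid-range
Highway is barrier,3rd order spatial,cubic,sine_hole,0,0.772,0.206,0.412,2.597,0.4451,,≥ Mid-range
Highway is barrier,3rd order spatial + rater,sine_hole,gaussian,0.043,0.180,0.641,2.439,1.0e-6,0.4690,5.37,≥ Mid-range
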