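item,detrending,auc_large_scale,auc_full,pct_change_rater,pct_change_scale
Garbage,3rd order spatial,0.755,0.856,,13.4
Garbage,3rd order spatial + rater,0.874,0.919,7.36,5.1
Abandoned cars,3rd order spatial,0.881,0.996,,13.1
Abandoned cars,3rd order spatial + rater,0.952,0.994,-0.2,4.4
Building conditions ≥ moderate,3rd order spatial,0.852,0.902,,5.9
Building conditions ≥ moderate,3rd order spatial + rater,0.880,0.916,1.55,4.1
Yard conditions ≥ moderate,3rd order spatial,0.897,0.934,,4.1
Yard conditions ≥ moderate,3rd order spatial + rater,0.921,0.946,1.28,2.7
Dumpster,3rd order spatial,0.714,0.842,,17.9
Dumpster,3rd order spatial + rater,0.714,0.849,0.83,18.9
Graffiti,3rd order spatial,0.871,0.914,,4.9
Graffiti,3rd order spatial + rater,0.887,0.923,0.98,4.1
Boarded/burned building,3rd order spatial,0.851,0.914,,7.4
Boarded/burned building,3rd order spatial + rater,0.850,0.915,0.11,7.6
Outdoor seating,3rd order spatial,0.562,0.735,,30.8
Outdoor seating,3rd order spatial + rater,0.679,0.767,4.35,13
Team sports,3rd order spatial,0.591,0.915,,54.8
Team sports,3rd order spatial + rater,0.683,0.894,-2.3,30.9
Yard decorations,3rd order spatial,0.667,0.825,,23.7
Yard decorations,3rd order spatial + rater,0.708,0.852,3.27,20.3
Fences,3rd order spatial,0.710,0.884,,24.5
Fences,3rd order spatial + rater,0.736,0.897,1.47,21.9
Sidewalk present,3rd order spatial,0.814,0.950,,16.7
Sidewalk present,3rd order spatial + rater,0.814,0.943,-0.74,15.8
Complete sidewalk,3rd order spatial,0.683,0.842,,23.3
Complete sidewalk,3rd order spatial + rater,0.726,0.855,1.54,17.8
Sidewalk condition,3rd order spatial,0.662,0.771,,16.5
Sidewalk condition,3rd order spatial + rater,0.697,0.775,0.52,11.2
Sidewalk width,3rd order spatial,0.830,0.897,,8.1
Sidewalk width,3rd order spatial + rater,0.831,0.901,0.45,8.4
Sidewalk from curb distance,3rd order spatial,0.586,0.978,,66.9
Sidewalk from curb distance,3rd order spatial + rater,0.724,0.914,-6.54,26.2
Car obstruction,3rd order spatial,0.626,0.879,,40.4
Car obstruction,3rd order spatial + rater,0.663,0.881,0.23,32.9
Garbage can obstruction,3rd order spatial,0.674,0.929,,37.8
Garbage can obstruction,3rd order spatial + rater,0.695,0.917,-1.29,31.9
Pole or sign obstruction,3rd order spatial,0.592,0.900,,52
Pole or sign obstruction,3rd order spatial + rater,0.726,0.876,-2.67,20.7
Other obstruction,3rd order spatial,0.689,0.870,,26.3
Other obstruction,3rd order spatial + rater,0.694,0.871,0.11,25.5
Curb cuts,3rd order spatial,0.559,0.710,,27
Curb cuts,3rd order spatial + rater,0.669,0.716,0.85,7
Clear intersection,3rd order spatial,0.681,0.851,,25
Clear intersection,3rd order spatial + rater,0.684,0.852,0.12,24.6
Pedestrian crossing sign,3rd order spatial,0.669,0.827,,23.6
Pedestrian crossing sign,3rd order spatial + rater,0.664,0.809,-2.18,21.8
Pedestrian signal,3rd order spatial,0.651,0.908,,39.5
Pedestrian signal,3rd order spatial + rater,0.679,0.897,-1.21,32.1
Pedestrian crossing marks,3rd order spatial,0.731,0.871,,19.2
Pedestrian crossing marks,3rd order spatial + rater,0.725,0.860,-1.26,18.6
Type of pedestrian crosswalk marks,3rd order spatial,0.697,0.931,,33.6
Type of pedestrian crosswalk marks,3rd order spatial + rater,0.709,0.934,0.32,31.7
Traffic signal type,3rd order spatial,0.661,0.841,,27.2
Traffic signal type,3rd order spatial + rater,0.699,0.838,-0.36,19.9
One-way street,3rd order spatial,0.789,0.931,,18
One-way street,3rd order spatial + rater,0.793,0.923,-0.86,16.4
Number of lanes,3rd order spatial,0.676,0.920,,36.1
Number of lanes,3rd order spatial + rater,0.674,0.948,3.04,40.7
Presence of highway,3rd order spatial,0.838,0.993,,18.5
Presence of highway,3rd order spatial + rater,0.838,0.993,0,18.5
Highway is barrier,3rd order spatial,0.563,0.833,,48
Highway is barrier,3rd order spatial + rater,0.479,0.583,-30.01,21.7
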