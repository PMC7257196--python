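item,group,n_yes,pct_yes
Garbage,neighborhood physical disorder,3285,41.2
Abandoned cars,neighborhood physical disorder,13,0.2
Building conditions ≥ moderate,neighborhood physical disorder,6349,86.3
Yard conditions ≥ moderate,neighborhood physical disorder,5388,87.7
Dumpster,neighborhood physical disorder,706,8.9
Graffiti,neighborhood physical disorder,904,11.3
Boarded/burned building,neighborhood physical disorder,502,6.3
Outdoor seating,neighborhood physical disorder,2131,27.1
Team sports,neighborhood physical disorder,187,2.4
Yard decorations,neighborhood physical disorder,3932,49.9
Fences,neighborhood physical disorder,6390,80.3
Sidewalk present,sidewalk,5462,68.2
Complete sidewalk,sidewalk,4948,90.4
Sidewalk condition,sidewalk,3535,64.7
Sidewalk width,sidewalk,872,15.9
Sidewalk from curb distance,sidewalk,71,1.3
Car obstruction,sidewalk,340,6.2
Garbage can obstruction,sidewalk,301,5.5
Pole or sign obstruction,sidewalk,262,5.8
Other obstruction,sidewalk,445,8.1
Curb cuts,sidewalk,2585,52.1
Clear intersection,intersection,4741,60.1
Pedestrian crossing sign,intersection,860,17.9
Pedestrian signal,intersection,718,15.1
Pedestrian crossing marks,intersection,2975,64.0
Type of pedestrian crosswalk marks,intersection,2076,68.4
Traffic signal type,intersection,3438,73.8
One-way street,intersection,846,10.7
Number of lanes,intersection,1183,14.9
Presence of highway,intersection,579,7.3
Highway is barrier,intersection,29,19.9
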