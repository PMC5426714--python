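code,label,a_dirus,a_maculatus,a_minimus,b_insecticide
11,Evergreen Forest,10,7,8,1
13,Mixed deciduous Forest,10,7,8,1
15,Dry Dipterocarp Forest,10,7,8,1
16,Gallery Forest,3,9,10,1
17,Coniferous forest,1,1,1,1
18,Mixed Broad-Leaved Forest,10,9,9,1
19,Forest Plantation,6,7,7,1
191,Rubber,8,6,8,2
192,Eucalyptus,5,5,5,2
193,Kathin nalong wood,6,6,6,1
194,Teak wood,6,6,6,2
195,Aquilaria crassna wood,8,6,8,3
21,Bamboo Forest,7,7,7,1
22,Unstocked Forest,1,1,1,1
24,Plateau,2,2,2,1
31,Savannah,1,1,1,1
32,Scrubland,4,4,4,1
41,Rice Paddy,2,7,7,3
411,Irrigated Paddy,1,7,7,3
42,Other Agriculture,3,3,3,2
421,Cassava,1,1,4,1
422,Sugarcane,1,1,4,1
423,Morinda citrifolia,1,1,1,4
424,Coffee,2,2,2,2
425,Maize,1,1,1,2
426,Hibiscus sabdariffa,1,1,1,4
427,Bastard Cardamom,1,1,1,2
428,Cotton,1,1,1,2
429,Tea,1,1,1,2
430,Mulberry,2,2,2,4
431,Job's Tear,1,1,1,4
432,Coconut,1,1,1,4
434,Banana,1,1,1,4
435,Sweet Potato,1,1,1,2
436,Groundnut,1,1,1,3
437,Citrus,2,3,3,4
440,Other Fruit tree,2,3,3,4
441,Palm,1,1,1,1
51,Rocked,1,1,1,1
52,Grassland,2,4,2,1
521,Pastures,2,4,2,1
53,Wetlands,4,10,8,1
54,Urban area,0,0,0,1
541,Cemetery,1,1,1,1
542,Industrial,0,0,0,1
543,Mine,1,1,1,1
544,Airport,1,1,1,1
545,Stadium (Any Sport),1,1,1,1
546,Waste dump,1,1,1,1
547,National Protection,10,10,10,1
548,Culture Zone,1,1,1,2
55,Island,4,10,8,1
550,Other concession,1,1,1,1
61,Water body,6,10,8,1
611,Reservoir,2,2,2,1
612,Irrigated area,1,7,7,1
613,Flood area,2,2,2,1
2104,Unpaved Road,1,1,1,1
21011,Paved Road,0,0,0,1
21021,Street Town,0,0,0,1
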