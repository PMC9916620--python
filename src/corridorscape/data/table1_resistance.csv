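land_class,agriculture,pct_all_cv,pct_interior,low,medium,high
Grassland,,27.91,9.82,1,1,1
Natural,,11.95,3.87,1,1,1
Rice,Y,2.67,4.11,1,1,1
Mixed Pasture,Y,1.28,1.87,1,2,2
Olives,Y,0.29,0.42,1,2,2
Sunflowers,Y,0.29,0.45,1,2,2
Carrots,Y,0.20,0.31,2,4,6
"Corn, Sorghum and Sudan",Y,3.63,5.59,4,5,6
"Plums, Prunes and Apricots",Y,0.51,0.79,5,6,7
Wheat,Y,1.01,1.55,2,6,9
Urban,,7.67,8.74,7,8,9
Pomegranates,Y,0.19,0.30,6,12,17
Beans (Dry),Y,0.24,0.36,12,14,16
Agricultural Margin,,6.15,8.98,7,15,20
Urban Greenspace,,0.27,0.30,7,15,20
Potatoes and Sweet Potatoes,Y,0.18,0.28,16,16,17
"Melons, Squash and Cucumbers",Y,0.34,0.52,16,17,18
Alfalfa and Alfalfa Mixtures,Y,3.06,4.69,10,20,29
Other,,8.73,13.20,19,22,25
Grapes,Y,3.76,5.75,22,24,26
Safflower,Y,0.24,0.36,21,26,31
Tomatoes,Y,1.74,2.67,28,29,30
Almonds,Y,6.69,10.30,27,32,37
Cherries,Y,0.25,0.39,32,33,34
Onions and Garlic,Y,0.23,0.35,30,34,39
Pistachios,Y,2.01,3.08,30,34,39
Peaches/Nectarines,Y,0.47,0.72,34,35,36
Walnuts,Y,2.13,3.27,35,38,40
Bare Soil,,1.09,0.60,20,40,100
Urban Impervious,,0.89,1.25,10,40,100
Cotton,Y,1.29,1.99,42,45,48
Citrus,Y,1.39,2.13,87,92,98
Water,,1.24,0.99,100,100,100
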