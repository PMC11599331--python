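taxon,group,asin_ba,freq_ba,asin_kp,freq_kp
Agaricus type,B,170831,68.4,25243,69.6
Agrocybe,B,9489,85.4,6843,89.9
Alternaria,A,33766,96.9,46019,96.4
Amphisphaeria,A,1835,56.5,1365,52.9
Arthrinium,A,2641,90.1,13194,94.6
Ascobolus,A,68,17,28,12
Ascochyta,A,5342,34.7,2846,70.7
Aspergillus/Penicillium,A,2141,37.1,6827,63.8
Asterosporium,A,,,25,10.1
Bipolaris,A,264,49,84,12.7
Botrytis,A,1764,50.3,1051,59.8
Bovista,B,716,34.7,23855,63
Caloplaca,A,1610,31,362,25
Camarosporum,A,47,6.8,,
Camptophora,A,4,1,,
Cercospora,A,968,26.9,595,33.3
Cerebella,A,537,22.4,452,27.5
Cladosporium,A,1649583,100,726757,100
Coprinus,B,7367,85,5317,80.8
Coprinus type,B,172948,98,124548,96
Corynespora,A,,,6,1.4
Cucurbitaria,A,1152,37.8,,
Curvularia,A,71,18.4,299,24.3
Diatrypaceae,A,3839,32.7,1920,21.4
Drechslera,A,120,22.4,213,44.2
Epicoccum,A,14863,95.9,11453,97.5
Exosporiella type,A,309,35.7,28,3.6
Exosporium,A,10482,66.3,1523,71.4
Fomes,B,8714,28.6,,
Fusarium,A,3864,16.7,3543,60.9
Fusicladium,A,351,60.5,135,39.9
Ganoderma,B,29157,68.7,22072,79.3
Helicospores,A,119,21.8,742,42.4
Chaetomium,A,796,74.8,1005,75.4
Chalastospora,A,20,2.7,,
Leptosphaeria type,A,108775,99.3,22642,94.6
Massaria,A,47,13.6,223,43.5
Melanospora,A,143,36.1,341,57.2
Myxomycetes,P,29574,79.9,25141,96.4
Neohendersonia,A,52,16.3,144,41.7
Nigrospora,A,1326,92.2,721,84.4
Oidium type,A,53575,68,12263,81.2
Oncopodiella,A,24,8.2,2,1.1
Panaeolina,B,175,21.4,1,0.7
Panaeolus,B,611,48.6,453,48.9
Periconia,A,3041,94.2,2366,86.6
Peronospora,Ch,722,67.7,1071,75.4
Pithomyces,A,2889,73.8,1596,71.7
Pleospora,A,4069,95.9,4074,82.6
Polythrincium,A,312,45.6,128,34.8
Puccinia,B,147,12.9,930,77.5
Saccobolus,A,7,2,,
Sordaria,A,154,38.8,291,56.5
Spegazzinia,A,73,19,27,10.1
Splanchonema,A,176,34.4,,
Sporidesmium,A,194,44.6,28,8
Sporormiella,A,75,22.4,78,15.6
Stemphylium,A,2726,62.6,1937,79.7
Teliospores,B,,,30,12.3
Tetraploa,A,1,0.3,7,25.7
Tilletia,B,4,1.4,149,3.6
Torula,A,2639,85.4,3226,92.4
Uredinospores,B,2104,43.5,498,53.3
Urocystis,B,170,25.5,129,24.6
Ustilago,B,6774,65.6,1582,29
Venturia,A,304,21.4,,
Xylariaceae,A,11706,90.5,5436,77.5
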