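taxon,site,start_doy,end_doy,length_days,ssin,peak_value,peak_doy,high_days
Agaricus type,BA,259,304,46,154457,14517,289,46
Agaricus type,KP,219,292,73,22851,2494,281,36
Agrocybe,BA,163,321,159,8545,410,277,28
Agrocybe,KP,159,318,159,6162,273,306,16
Alternaria,BA,170,299,130,30394,820,239,90
Alternaria,KP,166,297,131,41414,1668,261,120
Arthrinium,BA,74,295,222,2386,48,222,0
Arthrinium,KP,119,289,170,11863,1885,161,19
Ascochyta,BA,133,307,175,4796,565,137,14
Ascochyta,KP,117,303,186,2526,115,258,1
Aspergillus/Penicillium,BA,126,295,170,1888,1462,217,3
Aspergillus/Penicillium,KP,86,262,176,6119,79,97,0
Cladosporium,BA,96,323,228,1632471,41841,187,151
Cladosporium,KP,128,303,175,653380,32541,178,77
Coprinus,BA,162,318,157,6586,342,279,17
Coprinus,KP,131,322,191,4790,336,305,13
Coprinus type,BA,144,311,168,155746,5985,279,150
Coprinus type,KP,130,308,178,111616,5336,247,122
Epicoccum,BA,166,307,142,13363,516,306,46
Epicoccum,KP,166,308,142,10333,456,261,32
Fusarium,BA,159,262,104,3452,357,240,13
Fusarium,KP,116,312,196,3194,162,68,6
Ganoderma,BA,169,295,127,26194,549,224,102
Ganoderma,KP,164,300,136,19862,433,257,84
Leptosphaeria type,BA,134,307,174,98102,3984,183,144
Leptosphaeria type,KP,116,303,187,20339,826,212,73
Myxomycetes,BA,236,312,77,26221,1652,286,50
Myxomycetes,KP,130,315,185,22711,2488,290,53
Oidium type,BA,164,226,63,48264,6110,184,41
Oidium type,KP,113,230,117,11023,709,131,30
Periconia,BA,62,293,232,2712,74,281,0
Periconia,KP,77,307,230,2133,60,142,0
Pleospora,BA,91,326,236,3643,118,329,2
Pleospora,KP,90,298,208,3697,467,270,8
Torula,BA,74,289,216,2377,60,170,0
Torula,KP,83,290,207,2901,79,132,0
Xylariaceae,BA,167,308,142,10533,464,259,34
Xylariaceae,KP,160,312,152,4871,160,259,7
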