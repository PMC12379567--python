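# Reference female growth table, v1. Wet organ masses (g); bone includes marrow,
# excludes cartilage. rest_g = 1000*bw_kg - (bone+brain+liver+kidney) - 1000*plasma_L.
age_y,bw_kg,bone_g,brain_g,liver_g,kidney_g,rest_g,plasma_L
0,3.3,370,380,130,25,2255,0.14
0.25,5.6,500,560,180,35,4085,0.24
0.5,7.2,650,720,230,45,5245,0.31
1,9.5,850,950,300,60,6930,0.41
2,12.0,1200,1120,380,75,8705,0.52
5,18.0,2000,1240,560,110,13320,0.77
10,33.0,3600,1290,830,180,25680,1.42
12,41.0,4500,1300,950,200,32290,1.76
15,54.0,6000,1300,1200,240,42940,2.32
20,60.0,6800,1300,1400,275,47645,2.58
50,60.0,6800,1300,1400,275,47645,2.58
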