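ingredient,in_s1,in_s2,in_s3
emodin,1,1,1
chrysophanol,1,1,1
chrysarobin,0,0,1
rhein,1,1,1
danthron,1,0,1
polygonumnolide c2,0,0,1
emodin dianthrone,0,0,1
aloe emodin,1,1,0
luteolin,0,1,0
physcion,1,1,0
apigenin,1,0,0
emodin 8 methyl ether,1,0,0
citreorosein,1,0,0
emodin 3 methyl ether,1,0,0
fallacinol,1,0,0
2 acetylemodin,1,0,0
hexadecanoic acid methyl ester,1,0,0
octadecanoic acid methyl ester,1,0,0
docosanoic acid methyl ester,1,0,0
4 hydroxybenzaldehyde,1,0,0
"2,5 dimethyl 7 hydroxychromone",1,0,0
hydroxymaltol,1,0,0
butanedioic acid,1,0,0
"emodin 6,8 dimethylether",1,0,0
hexanoic acid,1,0,0
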