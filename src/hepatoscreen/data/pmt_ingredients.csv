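id,name,smiles,label
pmt01,emodin,CC1=CC2=C(C(=C1)O)C(=O)C3=C(C2=O)C=C(C=C3O)O,
pmt02,chrysophanol,CC1=CC2=C(C(=C1)O)C(=O)C3=C(C2=O)C=CC=C3O,
pmt03,rhein,C1=CC2=C(C(=C1O)O)C(=O)C3=CC(=CC(=C3C2=O)O)C(=O)O,
pmt04,danthron,C1=CC2=C(C(=C1)O)C(=O)C3=C(C2=O)C=CC=C3O,
pmt05,aloe emodin,C1=CC2=C(C(=C1)O)C(=O)C3=C(C2=O)C=C(C=C3O)CO,
pmt06,luteolin,C1=CC(=C(C=C1C2=CC(=O)C3=C(C=C(C=C3O2)O)O)O)O,
pmt07,physcion,CC1=CC2=C(C(=C1)O)C(=O)C3=C(C2=O)C=C(C=C3O)OC,
pmt08,apigenin,C1=CC(=CC=C1C2=CC(=O)C3=C(C=C(C=C3O2)O)O)O,
pmt09,emodin 8 methyl ether,,
pmt10,citreorosein,,
pmt11,emodin 3 methyl ether,,
pmt12,fallacinol,,
pmt13,2 acetylemodin,,
pmt14,hexadecanoic acid methyl ester,CCCCCCCCCCCCCCCC(=O)OC,
pmt15,octadecanoic acid methyl ester,CCCCCCCCCCCCCCCCCC(=O)OC,
pmt16,docosanoic acid methyl ester,CCCCCCCCCCCCCCCCCCCCCC(=O)OC,
pmt17,4 hydroxybenzaldehyde,C1=CC(=CC=C1C=O)O,
pmt18,"2,5 dimethyl 7 hydroxychromone",CC1=CC(=O)C2=C(O1)C=C(O)C=C2C,
pmt19,hydroxymaltol,CC1=C(O)C(=O)C(O)=CO1,
pmt20,butanedioic acid,C(CC(=O)O)C(=O)O,
pmt21,"emodin 6,8 dimethylether",,
pmt22,hexanoic acid,CCCCCC(=O)O,
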