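CC1=CC2=C(C(=C1)O)C(=O)C3=C(C2=O)C=C(C=C3O)O	emodin
CC1=CC2=C(C(=C1)O)C(=O)C3=C(C2=O)C=CC=C3O	chrysophanol
C1=CC2=C(C(=C1O)O)C(=O)C3=CC(=CC(=C3C2=O)O)C(=O)O	rhein
C1=CC2=C(C(=C1)O)C(=O)C3=C(C2=O)C=CC=C3O	danthron
C1=CC2=C(C(=C1)O)C(=O)C3=C(C2=O)C=C(C=C3O)CO	aloe emodin
CC1=CC2=C(C(=C1)O)C(=O)C3=C(C2=O)C=C(C=C3O)OC	physcion
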