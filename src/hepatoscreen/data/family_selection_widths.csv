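family,raw,all_relevant,pruned
FP,1024,117,117
ExtFP,1024,111,111
EStateFP,79,13,12
GraphFP,1024,83,73
MACCSFP,166,59,52
PubchemFP,881,77,58
SubFP,307,25,22
SubFPC,307,18,15
KRFP,4860,61,49
KRFPC,4860,38,26
AP2D,780,38,34
APC2D,780,33,17
2D Descriptor,1444,138,91
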