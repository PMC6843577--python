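name,source
emodin,hili_dataset
chrysophanol,hili_dataset
rhein,hili_dataset
aloe emodin,hili_dataset
luteolin,hili_dataset
physcion,hili_dataset
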