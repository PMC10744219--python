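region,mean_pct,sd_pct
base,32.8,4.1
mid,38.1,5.8
apex,28.6,7.7
overall,33.4,4.3
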