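species	variant	bands
Oxynotus centrina	variant_1	510
Prionace glauca	variant_1	400,110
Scyliorhinus canicula	variant_1	400,150
Mustelus mustelus	variant_1	390,180,120
Xiphias gladius	clade_I	240,220,170
Xiphias gladius	clade_II	280,220,170
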