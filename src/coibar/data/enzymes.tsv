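name	site
HpaII	C^CGG
HinfI	G^ANTC
MboI	^GATC
RsaI	GT^AC
HindIII	A^AGCTT
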