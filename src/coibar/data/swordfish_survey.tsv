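sample_id	group	declared_species	matched_species	matched_reference	identity_pct
XIP1	reference	Xiphias gladius	Xiphias gladius	JN083390	100.00
XIP2	reference	Xiphias gladius	Xiphias gladius	JN049558	99.71
MUS1	reference	Mustelus mustelus	Mustelus mustelus	JN641215	99.39
MUS2	reference	Mustelus mustelus	Mustelus mustelus	JN641214	99.24
OXY1	reference	Oxynotus centrina	Oxynotus centrina	JF834320	98.96
OXY2	reference	Oxynotus centrina	Oxynotus centrina	JF834320	98.66
PRI1	reference	Prionace glauca	Prionace glauca	KJ146044	99.85
PRI2	reference	Prionace glauca	Prionace glauca	MH719984	99.83
SCY1	reference	Scyliorhinus canicula	Scyliorhinus canicula	KJ205311	99.70
SCY2	reference	Scyliorhinus canicula	Scyliorhinus canicula	KJ205311	99.85
X1	2010	Xiphias gladius	Xiphias gladius	JN083389	100.00
X2	2010	Xiphias gladius	Xiphias gladius	JN083387	100.00
X3	2010	Xiphias gladius	Xiphias gladius	JN049559	100.00
X4	2010	Xiphias gladius	Xiphias gladius	JN083397	100.00
X5	2010	Xiphias gladius	Xiphias gladius	JN083387	100.00
X6	2010	Xiphias gladius	Xiphias gladius	JN049559	100.00
X7	2010	Xiphias gladius	Xiphias gladius	JN049559	100.00
X8	2010	Xiphias gladius	Xiphias gladius	JN083387	100.00
X9	2010	Xiphias gladius	Xiphias gladius	JN083393	100.00
X10	2010	Xiphias gladius	Xiphias gladius	JN049559	100.00
X11	2010	Xiphias gladius	Xiphias gladius	JN083393	100.00
X12	2010	Xiphias gladius	Xiphias gladius	JN083387	100.00
X13	2010	Xiphias gladius	Prionace glauca	MH719984	99.83
X14	2010	Xiphias gladius	Xiphias gladius	JN083386	100.00
X15	2010	Xiphias gladius	Xiphias gladius	JN083387	100.00
Y1	2018	Xiphias gladius	Xiphias gladius	JN049558	99.71
Y2	2018	Xiphias gladius	Xiphias gladius	JN083390	99.71
Y3	2018	Xiphias gladius	Xiphias gladius	JN083387	99.71
Y4	2018	Xiphias gladius	Xiphias gladius	JN049558	99.71
Y5	2018	Xiphias gladius	Xiphias gladius	JN083387	99.85
Y6	2018	Xiphias gladius	Xiphias gladius	JN083387	99.71
Y7	2018	Xiphias gladius	Mustelus mustelus	JN641214	99.39
Y8	2018	Xiphias gladius	Xiphias gladius	JN049558	99.85
Y9	2018	Xiphias gladius	Xiphias gladius	JN083387	99.71
Y10	2018	Xiphias gladius	Oxynotus centrina	JF834320	98.07
Y11	2018	Xiphias gladius	Xiphias gladius	JN083387	99.12
Y12	2018	Xiphias gladius	Xiphias gladius	JN049558	99.85
Y13	2018	Xiphias gladius	Xiphias gladius	JN083390	99.41
Y14	2018	Xiphias gladius	Xiphias gladius	JN083387	98.97
Y15	2018	Xiphias gladius	Prionace glauca	MH194484	99.39
Y16	2018	Xiphias gladius	Xiphias gladius	JN049558	99.27
Y17	2018	Xiphias gladius	Xiphias gladius	JN083387	99.85
Y18	2018	Xiphias gladius	Xiphias gladius	JN083390	99.27
Y19	2018	Xiphias gladius	Xiphias gladius	JN049558	99.71
Y20	2018	Xiphias gladius	Xiphias gladius	JN083387	99.56
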