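species	COX2	HPGDS	PTGES2	PGE2-9-OR	15-PGDH	PTGFS1	PTGFS2	PTGR1	PTGR2
A. margalefi	0	1	0	0	0	0	0	1	1
A. tamarense	0	1	1	0	0	0	0	1	0
A. carterae	0	0	1	0	0	0	0	1	0
A. massartii	1	1	1	1	0	0	0	1	0
G. australes	0	1	1	0	0	0	0	1	0
G. foliaceum	0	1	1	0	0	1	1	1	1
K. brevis	0	1	1	1	1	0	0	1	1
K. foliaceum	0	1	0	0	0	1	0	1	0
L. polyedra	0	1	1	1	0	0	0	1	0
N. scintillans	0	0	1	0	0	0	0	1	1
P. beii	0	0	1	0	0	0	0	1	0
P. glacialis	1	0	1	0	0	0	0	1	0
S. hangoei	0	1	1	1	0	1	0	1	0
T. jolla	0	0	1	0	0	0	0	1	0
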