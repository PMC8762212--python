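tsRNA_ID	Type	tRFdb_ID	Length	logFC	padj	Regulation
tiRNA-1:33-Pro-CGG-1	tiRNA-5	-	33	2.667854	0.009664	Up
tRF-1:22-Ser-GCT-1-M4	tRF-5b	-	22	2.336799	0.05431	Up
tRF-58:75-Gln-CTG-1-M7	tRF-3a	3007a	18	3.320385	0.044557	Up
tRF-69:86-Leu-CAA-1-M5	tRF-3a	3018a	18	3.881438	0.01871	Up
tRF-1:16-Leu-TAG-3	tRF-5a	-	16	1.627943	0.041306	Up
tRF-1:22-Ser-AGA-1-M3	tRF-5b	-	22	3.491182	0.00942	Up
tRF-1:32-Gly-ACC-1	tRF-5c	-	32	1.950371	0.044087	Up
tRF-1:22-Lys-TTT-1	tRF-5b	-	22	1.949221	0.046665	Up
tRF-60:76-Tyr-GTA-1-M5	tRF-3a	3046a	17	3.22135	0.069064	Up
tRF-1:28-Gly-GCC-1	tRF-5c	-	28	-1.47745	0.017336	Down
tRF-1:23-Glu-CTC-1-M3	tRF-5b	5022b	23	-3.07916	0.001160	Down
tRF-1:28-Glu-TTC-2	tRF-5c	-	28	-1.81963	0.009118	Down
tRF-1:31-His-GTG-1	tRF-5c	-	31	-1.67124	0.015401	Down
tRF-1:14-Gly-CCC-1	tRF-5a	-	14	-2.34437	0.008618	Down
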