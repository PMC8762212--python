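tsRNA_ID	Type	tRFdb_ID	Length	logFC	padj	Regulation
tRF-59:75-Pro-AGG-1-M4	tRF-3a	-	17	4.186784	0.024808	Up
tiRNA-1:34-Glu-TTC-3	tiRNA-5	-	34	4.124974	0.001015	Up
tRF-69:86-Leu-CAA-1-M5	tRF-3a	3018a	18	3.881438	0.01871	Up
tRF-1:15-Ala-AGC-1-M3	tRF-5a	-	15	3.739387	0.033242	Up
tRF-1:22-Ser-AGA-1-M3	tRF-5b	-	22	3.625968	0.002213	Up
tiRNA-1:34-Glu-CTC-2	tiRNA-5	-	34	3.58281	0.006484	Up
tRF-58:75-Pro-AGG-1-M4	tRF-3a	3003a	18	3.443005	0.045347	Up
tiRNA-1:34-Glu-CTC-1	tiRNA-5	-	34	3.400312	0.003704	Up
tRF-58:75-Gln-CTG-1-M7	tRF-3a	3007a	18	3.320385	0.044557	Up
tiRNA-1:34-Ala-CGC-5	tiRNA-5	-	34	3.300042	0.0144	Up
tRF-1:28-His-GTG-2	tRF-5c	-	28	-2.24893	0.036493	Down
tiRNA-1:34-His-GTG-2	tiRNA-5	-	34	-2.25266	0.00901	Down
tRF-1:30-Gly-TCC-1	tRF-5c	-	30	-2.41074	0.004686	Down
tRF-1:31-Gly-TCC-1	tRF-5c	-	31	-2.42949	0.010598	Down
tRF-1:30-His-GTG-2	tRF-5c	-	30	-2.73888	0.001015	Down
tRF-1:22-Gly-GCC-2-M3	tRF-5b	5004a	22	-2.78403	0.018232	Down
tRF-1:29-His-GTG-2	tRF-5c	-	29	-2.912	0.001015	Down
tRF-1:24-Gly-GCC-2-M3	tRF-5b	-	24	-2.96808	0.001015	Down
tRF-1:16-Gly-CCC-1	tRF-5a	-	16	-3.02596	0.018232	Down
tRF-1:23-Glu-CTC-1-M3	tRF-5b	5022b	23	-3.10811	0.008184	Down
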