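# Printed cis-regulation table of the allergic-rhinitis nasal mucosa lncRNA
# microarray study (GEO accession GSE159415): differentially expressed lncRNAs
# and the co-expressed mRNAs whose loci lie within 100 kbp of the lncRNA locus.
# Transcribed by hand from the typeset table, whose rows run together; the
# run-on resolves to 41 pairs over 35 distinct lncRNAs per the study's stated
# counts. One run-on fragment (lnc-MARCKS-7 / BMS1P6, r 0.916819, no
# chromosome) breaks the table's sort order and duplicates the endpoints of
# two other rows; it is treated as a typesetting artifact and omitted.
# Transcription flagged for human review. chromosome "-" = not printed.
chromosome	correlation	lncrna_id	mrna_id
5	0.987369	lnc-XRCC4-6	VCAN
5	0.986823	lnc-IGIP-2	CTB-131B5.2
3	0.986734	lnc-TMEM207-2	CLDN1
16	0.986412	lnc-HPR-1	HP
2	0.983264	lnc-CALM2-10	MCFD2
1	0.981938	lnc-FMO6P-2	FMO2
1	0.981073	lnc-F5-1	SELP
10	0.97774	lnc-DLG5-4	KCNMA1
7	0.974997	lnc-FAM185A-3	LRRC17
10	0.966048	lnc-CXCL12-4	CXCL12
4	0.964856	lnc-MTNR1A-2	FAT1
9	0.964309	lnc-STOM-7	GGTA1P
4	0.96054	lnc-STIM2-11	PCDH7
10	0.950211	lnc-C10orf68-7	C10orf68
11	0.94865	lnc-GUCY1A2-1	GUCY1A2
2	0.946103	lnc-LYPD1-2	NCKAP5
16	0.945882	lnc-UMOD-2	GP2
16	0.944974	lnc-HPR-1	HPR
5	0.941399	lnc-TAS2R1-24	SEMA5A
11	0.932664	lnc-CRTAM-1	C11orf63
6	0.931226	lnc-ME1-2	PGM3
2	0.92093	lnc-AC023469.1.1-2	RND3
4	0.917134	lnc-MUC7-1	MUC7
21	0.910659	lnc-ADAMTS1-2	ADAMTS5
11	0.904913	lnc-FADD-2	ANO1
4	0.891984	lnc-MUC7-1	SMR3B
1	0.890773	lnc-C8B-1	DAB1
9	0.886791	lnc-ANKRD18A-7	CNTNAP3
2	0.88018	lnc-OBFC2A-13	MYO1B
-	0.863629	lnc-MARCKS-7	RP11-782C8.5
4	0.858795	lnc-MUC7-1	SMR3A
2	0.856086	lnc-EPHA4-4	EPHA4
1	0.837189	lnc-RAVER2-1	CACHD1
4	0.834533	lnc-MUC7-1	AMBN
13	0.829561	lnc-DNAJC3-1	DNAJC3
3	0.82015	lnc-CNTN6-2	AC090044.2
21	-0.8336	lnc-CBR1-3	RIMKLBP1
-	-0.85488	lnc-SEPT7L-5	BMS1P6
12	-0.87456	lnc-APOBEC1-2	APOBEC1
-	-0.88594	lnc-SEPT7L-5	RP11-782C8.5
9	-0.9127	lnc-STOM-7	RP11-477J21.6
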