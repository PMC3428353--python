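# Canonical-cysteine loss events in insect odorant-binding proteins:
# transcription of the reported per-event loss table for the Nasonia
# vitripennis OBP family and related insect OBPs (22 events).
# One event per line.  The source table prints per-row event and gene
# counts with one event per printed line; where its line breaks were not
# recoverable, the gene list is partitioned into events by species/clade
# coherence, preserving every per-row event and gene count.
# columns: lost_set	event_id	affected_genes (comma-separated)
C1	1	NvitOBP31
C1	2	NvitOBP64, DmelOBp59a
C2	3	AgamOBP38b
C2	4	AgamOBP42a
C5	5	NvitOBP38b, NvitOBP39b, NvitOBP40b, NvitOBP41b, NvitOBP42b, NvitOBP44b, NvitOBP45b
C5	6	ApisOBP11
C6	7	DmelOBP73a
C6	8	AcerASP4
C1/C3	9	AgamOBP34b, AgamOBP35b, AgamOBP36b, AgamOBP37b
C2/C5	10	NvitOBP27, NvitOBP56, NvitOBP58, NvitOBP59, NvitOBP60, NvitOBP61, NvitOBP62
C2/C5	11	NvitOBP38a, NvitOBP39a, NvitOBP40a, NvitOBP41a, NvitOBP42a, NvitOBP43, NvitOBP44a, NvitOBP45a, NvitOBP46a
C2/C5	12	DmelOBP8a, DmelOBP99c, DmelOBP99d
C2/C5	13	DmelOBP44a
C2/C5	14	AgamOBP39b
C2/C5	15	LtesOBP8
C2/C5	16	AmelOBP14, AmelOBP15, AmelOBP16, AmelOBP17, AmelOBP18, AmelOBP19, AmelOBP20, AmelOBP21
C2/C5	17	TcasOBP02, TcasOBP03, TcasOBP04, TcasOBP05, TcasOBP06, TcasOBP07, TcasOBP08, TcasOBP09, TcasOBP10, TcasOBP11, TcasOBP12, TcasOBP13, TcasOBP14, TcasOBP15, TcasOBP22, TcasOBP23, TcasOBP24, TcasOBP33, TcasOBP34, TcasOBP44
C4/C6	18	AgamOBP40a
C4/C6	19	AgamOBP45b
C2/C6	20	NvitOBP69
C5/C6	21	AgamOBP65
C4/C5/C6	22	AgamOBP16
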