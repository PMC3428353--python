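# Per-gene annotation of the 90 Nasonia vitripennis odorant-binding-protein
# genes: genomic scaffold, coding status, EST expression support and
# cysteine-scaffold subfamily, transcribed from the reported family summary.
# Known internal inconsistencies of the source (pseudogenes listed with full
# EST support; NvitOBP38 labelled Minus-C although grouped with the
# double-domain cluster elsewhere) are preserved verbatim, not corrected.
# notes: vestigial-second-domain = retains only remnants of a former 2nd
# domain; minus-C label applies to the 1st domain only.
name	scaffold	status	est_support	subfamily	notes
NvitOBP01	1	coding	yes	Classic
NvitOBP02	1	coding	yes	Classic
NvitOBP03	1	coding	yes	Classic
NvitOBP04	3	coding	none	Classic
NvitOBP05	3	pseudogene	none	Classic
NvitOBP06	5	coding	yes	Classic
NvitOBP07	9	coding	yes	Classic
NvitOBP08	9	coding	yes	Classic
NvitOBP09	9	coding	yes	Classic
NvitOBP10	9	coding	none	Classic
NvitOBP11	9	coding	yes	Classic
NvitOBP12	9	coding	yes	Classic
NvitOBP13	9	coding	yes	Classic
NvitOBP14	9	coding	none	Classic
NvitOBP15	9	coding	yes	Classic
NvitOBP16	9	coding	none	Classic
NvitOBP17	9	coding	yes	Classic
NvitOBP18	9	coding	yes	Classic
NvitOBP19	9	coding	yes	Classic
NvitOBP20	9	coding	yes	Classic
NvitOBP21	9	coding	none	Classic
NvitOBP22	9	coding	none	Classic
NvitOBP23	9	coding	yes	Classic
NvitOBP24	9	coding	none	Classic
NvitOBP25	9	coding	yes	Classic
NvitOBP26	9	coding	yes	Classic
NvitOBP27	9	coding	yes	Minus-C
NvitOBP28	9	coding	yes	Classic
NvitOBP29	9	coding	none	Classic
NvitOBP30	9	coding	yes	Classic
NvitOBP31	9	coding	none	Classic
NvitOBP32	9	coding	yes	Classic
NvitOBP33	9	pseudogene	yes	Classic
NvitOBP34	9	pseudogene	yes	Classic
NvitOBP35	9	coding	yes	Classic
NvitOBP36	9	coding	none	Classic
NvitOBP37	9	coding	yes	Classic
NvitOBP38	9	coding	yes	Minus-C
NvitOBP39	9	coding	partial	DoubleMinus-C
NvitOBP40	9	coding	yes	DoubleMinus-C
NvitOBP41	9	coding	yes	DoubleMinus-C
NvitOBP42	9	coding	none	DoubleMinus-C
NvitOBP43	9	coding	none	DoubleMinus-C	vestigial-second-domain
NvitOBP44	9	coding	yes	DoubleMinus-C
NvitOBP45	9	coding	yes	DoubleMinus-C
NvitOBP46	9	coding	yes	DoubleMinus-C
NvitOBP47	9	coding	yes	Classic
NvitOBP48	9	coding	yes	Double
NvitOBP49	9	coding	yes	Double
NvitOBP50	9	coding	yes	Classic
NvitOBP51	9	coding	yes	Classic
NvitOBP52	9	coding	yes	Classic
NvitOBP53	9	coding	yes	Classic
NvitOBP54	9	coding	yes	Classic
NvitOBP55	9	coding	yes	Classic
NvitOBP56	9	coding	yes	Minus-C
NvitOBP57	9	pseudogene	none	Classic
NvitOBP58	9	coding	yes	Minus-C
NvitOBP59	9	coding	partial	Minus-C
NvitOBP60	9	coding	yes	Minus-C
NvitOBP61	9	coding	none	Minus-C
NvitOBP62	9	coding	yes	Minus-C
NvitOBP63	9	incomplete	none	Classic
NvitOBP64	9	incomplete	none	Classic
NvitOBP65	18	coding	yes	Classic
NvitOBP66	18	coding	yes	Classic
NvitOBP67	20	coding	yes	Classic
NvitOBP68	20	pseudogene	none	Classic
NvitOBP69	24	coding	yes	Classic
NvitOBP70	30	coding	none	Classic
NvitOBP71	30	coding	yes	Classic
NvitOBP72	30	coding	partial	Classic
NvitOBP73	30	pseudogene	yes	Classic
NvitOBP74	33	pseudogene	yes	Classic
NvitOBP75	40	coding	yes	Classic
NvitOBP76	126	coding	none	Classic
NvitOBP77	153	coding	none	Classic
NvitOBP78	153	coding	none	Classic
NvitOBP79	153	coding	none	Classic
NvitOBP80	153	coding	none	Classic
NvitOBP81	153	coding	yes	Classic
NvitOBP82	153	coding	yes	Classic
NvitOBP83	153	coding	yes	Classic
NvitOBP84	153	coding	yes	Classic
NvitOBP85	163	coding	none	Classic
NvitOBP86	174	incomplete	yes	Classic
NvitOBP87	178	coding	none	Classic
NvitOBP88	178	coding	none	Classic
NvitOBP89	178	pseudogene	none	Classic
NvitOBP90	185	coding	yes	Classic
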