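id	name	signal_end	class	complete
PQ049256	AKH-1	21	neuropeptide	true
PQ049257	AKH-2	18	neuropeptide	true
PQ049260	ACP	21	neuropeptide	true
PQ049261	AT	23	neuropeptide	true
PQ049262	Ast-A	21	neuropeptide	true
PQ049263	MIP	20	neuropeptide	true
PQ049264	Ast-CC	20	neuropeptide	true
PQ049265	Ast-CCC	24	neuropeptide	true
PQ049266	Inotocin	18	neuropeptide	true
PQ049267	Calcitonin-B		neuropeptide	false
PQ049268	DH-31	20	neuropeptide	true
PQ049269	DH-46	21	neuropeptide	true
PQ049270	CAPA-PVK	18	neuropeptide	true
PQ049271	CCHa-1	24	neuropeptide	true
PQ049272	CCHa-2	18	neuropeptide	true
PQ049273	CNMa-A		neuropeptide	false
PQ049274	CNMa-B	21	neuropeptide	true
PQ049275	Crz	21	neuropeptide	true
PQ049276	CCAP	21	neuropeptide	true
PQ049277	CCRFa	23	neuropeptide	true
PQ049278	Elv	23	neuropeptide	true
PQ049279	FMRFa	19	neuropeptide	true
PQ049282	Hansolin	21	neuropeptide	true
PQ049283	ITG	25	neuropeptide	true
PQ049286	Kinin	23	neuropeptide	true
PQ049287	MS	19	neuropeptide	true
PQ049288	Nat	23	neuropeptide	true
PQ049289	NPF-1a	25	neuropeptide	true
PQ049290	NPF-1b		neuropeptide	false
PQ049291	NPF-2	22	neuropeptide	true
PQ049296	Orc-A	18	neuropeptide	true
PQ049297	Orc-B		neuropeptide	false
PQ049298	PDF	21	neuropeptide	true
PQ049299	PK	18	neuropeptide	true
PQ049300	Proctolin	21	neuropeptide	true
PQ049301	RFLamide	20	neuropeptide	true
PQ049302	RYamide	23	neuropeptide	true
PQ049303	sNPF	19	neuropeptide	true
PQ049304	SIFamide	21	neuropeptide	true
PQ049305	SMYamide	19	neuropeptide	true
PQ049306	SK	23	neuropeptide	true
PQ049307	TK	22	neuropeptide	true
PQ049308	Trissin	22	neuropeptide	true
PQ049258	ALP-1	22	neuropeptide_like	true
PQ049259	ALP-2		neuropeptide_like	false
PQ049280	FERLQ-like	19	neuropeptide_like	true
PQ049281	Flik	23	neuropeptide_like	true
PQ049293	NPLP-1	21	neuropeptide_like	true
PQ049294	CNPLP-1	25	neuropeptide_like	true
PQ300805	NVP-A	21	neuropeptide_like	true
PQ300806	NVP-B	25	neuropeptide_like	true
PQ049309	Bursicon-alpha		protein_hormone	false
PQ049310	EH-1	21	protein_hormone	true
PQ049311	EH-2	22	protein_hormone	true
PQ049312	GPA	25	protein_hormone	true
PQ049313	GPB	25	protein_hormone	true
PQ300807	IDLP-A	20	protein_hormone	true
PQ300808	IDLP-B	24	protein_hormone	true
PQ049316	ILP-1	22	protein_hormone	true
PQ049317	ILP-2	19	protein_hormone	true
PQ049318	ILP-3		protein_hormone	false
PQ049319	ILP-4	19	protein_hormone	true
PQ049320	ILP-5	20	protein_hormone	true
PQ049321	ILP-6	23	protein_hormone	true
PQ049284	ITP	21	protein_hormone	true
PQ049322	Neuroparsin		protein_hormone	false
PQ049323	PTTH	21	protein_hormone	true
PQ049324	iPTH	21	protein_hormone	true
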