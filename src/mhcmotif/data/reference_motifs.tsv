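source	allele	length	position	role	primary	secondary
pool_sequencing	HLA-A*0201	9	2	anchor	LM	IVATQ
pool_sequencing	HLA-A*0201	9	9	anchor	VL	MIAT
pool_sequencing	HLA-A*3001	9	2	anchor	YF	
pool_sequencing	HLA-A*3001	9	9	anchor	L	
pool_sequencing	HLA-A*3201	9	2	anchor		MLITVQS
pool_sequencing	HLA-A*3201	9	9	anchor		WIFYHT
pool_sequencing	HLA-A*6802	9	2	anchor		LMTVATQS
pool_sequencing	HLA-A*6802	9	9	anchor		LMTVAT
pool_sequencing	HLA-B*0702	9	2	anchor	P	
pool_sequencing	HLA-B*0702	9	9	anchor	L	FWYIVMA
pool_sequencing	HLA-B*0801	9	3	anchor	RK	
pool_sequencing	HLA-B*0801	9	5	anchor	RK	
pool_sequencing	HLA-B*0801	9	9	anchor	LIVM	
pool_sequencing	HLA-B*1501	9	2	anchor	QL	
pool_sequencing	HLA-B*1501	9	9	anchor	FY	
pool_sequencing	HLA-B*1503	9	2	anchor	QK	
pool_sequencing	HLA-B*1503	9	9	anchor	FY	
pool_sequencing	HLA-B*2705	9	2	anchor	R	
pool_sequencing	HLA-B*2705	9	9	anchor	KRLYANFMIK	
pool_sequencing	HLA-B*3501	9	2	anchor	P	
pool_sequencing	HLA-B*3501	9	9	anchor	YFMLI	WVA
pool_sequencing	HLA-B*5101	9	2	anchor	APG	
pool_sequencing	HLA-B*5101	9	9	anchor	VI	FWYLMA
pool_sequencing	HLA-B*5301	9	2	anchor	P	
pool_sequencing	HLA-B*5301	9	9	anchor	WFL	YIVMA
pool_sequencing	HLA-B*5401	9	2	anchor	P	
pool_sequencing	HLA-B*5401	9	9	anchor		FWYLIVMA
pool_sequencing	HLA-B*5801	9	2	anchor	AST	
pool_sequencing	HLA-B*5801	9	9	anchor	FW	
pool_sequencing	H-2-Db	9	5	anchor	N	
pool_sequencing	H-2-Db	9	9	anchor	LIVM	
pool_sequencing	H-2-Dd	9	2	anchor	G	
pool_sequencing	H-2-Dd	9	3	anchor	P	
pool_sequencing	H-2-Dd	9	5	anchor	RK	
pool_sequencing	H-2-Dd	9	9	anchor	LFI	
pool_sequencing	H-2-Kd	9	2	anchor	YF	
pool_sequencing	H-2-Kd	9	9	anchor	LIYM	
pool_sequencing	H-2-Kk	9	2	anchor	E	
pool_sequencing	H-2-Kk	9	9	anchor	LIVM	
combinatorial_library	HLA-A*0201	9	2	anchor	L	MQ
combinatorial_library	HLA-A*0201	9	9	anchor	VI	LA
combinatorial_library	HLA-A*3001	9	3	anchor	RK	
combinatorial_library	HLA-A*3001	9	9	anchor	KA	LVIY
combinatorial_library	HLA-A*3201	9	2	anchor	TMIQLVS	A
combinatorial_library	HLA-A*3201	9	9	anchor	FIYLW	
combinatorial_library	HLA-A*6802	9	2	anchor	VTS	LALMP
combinatorial_library	HLA-A*6802	9	9	anchor	VALI	
combinatorial_library	HLA-B*0702	9	2	anchor	P	VA
combinatorial_library	HLA-B*0702	9	9	anchor	LFAYI	M
combinatorial_library	HLA-B*0801	9	5	anchor	RHKF	
combinatorial_library	HLA-B*0801	9	6	anchor	F	RH
combinatorial_library	HLA-B*0801	9	9	anchor	LFMVIA	E
combinatorial_library	HLA-B*1501	9	9	anchor	FY	M
combinatorial_library	HLA-B*1503	9	2	anchor	QMK	LHASE
combinatorial_library	HLA-B*1503	9	9	anchor	F	MY
combinatorial_library	HLA-B*2705	9	2	anchor	R	
combinatorial_library	HLA-B*3501	9	2	anchor	PA	
combinatorial_library	HLA-B*3501	9	9	anchor	FYM	A
combinatorial_library	HLA-B*5101	9	2	anchor	PA	GQVS
combinatorial_library	HLA-B*5101	9	9	anchor	I	V
combinatorial_library	HLA-B*5301	9	2	anchor	PA	IY
combinatorial_library	HLA-B*5301	9	9	anchor	FC	IW
combinatorial_library	HLA-B*5401	9	2	anchor	A	P
combinatorial_library	HLA-B*5401	9	9	anchor	AV	
combinatorial_library	HLA-B*5801	9	2	anchor	STA	VG
combinatorial_library	HLA-B*5801	9	9	anchor	WFIY	MC
combinatorial_library	H-2-Db	9	5	anchor	N	L
combinatorial_library	H-2-Db	9	9	anchor	IML	VF
combinatorial_library	H-2-Dd	9	2	anchor	G	
combinatorial_library	H-2-Dd	9	3	anchor	P	
combinatorial_library	H-2-Dd	9	9	anchor	FLI	C
combinatorial_library	H-2-Kd	9	2	anchor	Y	
combinatorial_library	H-2-Kd	9	9	anchor	ILV	M
combinatorial_library	H-2-Kk	9	2	anchor	E	D
combinatorial_library	H-2-Kk	9	9	anchor	IV	FL
syfpeithi	HLA-A*0201	9	2	anchor	LM	
syfpeithi	HLA-A*0201	9	9	anchor	VL	
syfpeithi	HLA-A*3001	9	2	anchor	YF	
syfpeithi	HLA-A*3001	9	9	anchor	L	
syfpeithi	HLA-B*0702	9	2	anchor	P	
syfpeithi	HLA-B*0702	9	9	anchor	L	
syfpeithi	HLA-B*0801	9	3	anchor	K	
syfpeithi	HLA-B*1503	9	2	anchor	QK	
syfpeithi	HLA-B*1503	9	9	anchor	FY	
syfpeithi	HLA-B*2705	9	2	anchor	R	
syfpeithi	HLA-B*2705	9	9	anchor	FL	
syfpeithi	HLA-B*3501	9	2	anchor	P	
syfpeithi	HLA-B*3501	9	9	anchor	YFMLI	
syfpeithi	HLA-B*5101	9	2	anchor	APG	
syfpeithi	HLA-B*5101	9	9	anchor	VI	
syfpeithi	HLA-B*5301	9	2	anchor	P	
syfpeithi	HLA-B*5301	9	9	anchor	WFL	
syfpeithi	HLA-B*5401	9	2	anchor	P	
syfpeithi	HLA-B*5801	9	2	anchor	AST	
syfpeithi	HLA-B*5801	9	9	anchor	FW	
syfpeithi	H-2-Db	9	5	anchor	N	
syfpeithi	H-2-Db	9	9	anchor	LIVM	
syfpeithi	H-2-Dd	9	3	anchor	P	
syfpeithi	H-2-Dd	9	9	anchor	LFI	
syfpeithi	H-2-Kd	9	2	anchor	YF	
syfpeithi	H-2-Kd	9	9	anchor	LIV	
syfpeithi	H-2-Kk	9	2	anchor	E	
syfpeithi	H-2-Kk	9	9	anchor	IV	
automatic	HLA-A*0201	9	2	anchor	LM	
automatic	HLA-A*0201	9	9	anchor	VL	
automatic	HLA-A*3001	9	3	anchor	KR	
automatic	HLA-A*3001	9	9	anchor	K	
automatic	HLA-A*3201	9	2	anchor	MLTV	
automatic	HLA-A*3201	9	9	anchor	FIW	
automatic	HLA-A*6802	9	2	anchor	TV	
automatic	HLA-A*6802	9	9	anchor	V	
automatic	HLA-B*0702	9	2	anchor	P	
automatic	HLA-B*0702	9	9	anchor	FML	
automatic	HLA-B*0801	9	5	anchor	HKR	
automatic	HLA-B*0801	9	6	anchor	F	
automatic	HLA-B*0801	9	9	anchor	FIML	
automatic	HLA-B*1501	9	2	anchor	MLQ	
automatic	HLA-B*1501	9	9	anchor	FY	
automatic	HLA-B*1503	9	2	anchor	KMQ	
automatic	HLA-B*1503	9	9	anchor	FY	
automatic	HLA-B*2705	9	2	anchor	R	
automatic	HLA-B*2705	9	3	anchor	FLMWY	
automatic	HLA-B*2705	9	9	anchor	FIHKMLRY	
automatic	HLA-B*3501	9	2	anchor	P	
automatic	HLA-B*3501	9	9	anchor	FMY	
automatic	HLA-B*5101	9	2	anchor	P	
automatic	HLA-B*5101	9	9	anchor	IV	
automatic	HLA-B*5301	9	2	anchor	P	
automatic	HLA-B*5301	9	9	anchor	W	
automatic	HLA-B*5401	9	2	anchor	P	
automatic	HLA-B*5401	9	9	anchor	A	
automatic	HLA-B*5801	9	2	anchor	AST	
automatic	HLA-B*5801	9	9	anchor	W	
automatic	H-2-Db	9	5	anchor	N	
automatic	H-2-Db	9	9	anchor	IML	
automatic	H-2-Dd	9	2	anchor	G	
automatic	H-2-Dd	9	3	anchor	P	
automatic	H-2-Dd	9	9	anchor	FIMLRTV	
automatic	H-2-Kd	9	2	anchor	Y	
automatic	H-2-Kd	9	9	anchor	HIL	
automatic	H-2-Kk	9	2	anchor	E	
automatic	H-2-Kk	9	9	anchor	I	
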