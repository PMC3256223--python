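mirna	target	reference
mir-192	MDM2	Braun2008
mir-192	EGFR	Yantiss2009
mir-192	PIK3CA	Yantiss2009
mir-192	TP53	Georges2008
mir-192	PTEN	Kato2009
mir-192	CDKN1	Braun2008
mir-181c	AKT	Androulidaki2009
mir-181c	MYC	Wong2010
mir-489	CDKN1	Miller2009
mir-489	PIK3CA	Miller2009
mir-489	TP53	Miller2009
mir-489	AKT	Miller2009
mir-34a	MTOR	Pineau2010
mir-34a	ERK	Ichimura2010
mir-34a	MDM2	Okada2014
mir-34a	PIK3R1	Pineau2010
mir-34a	EGFR	Li2009
mir-34a	RPS6KA5	Christoffersen2010
mir-34a	CAMK	Pineau2010
mir-34a	TP53	Yamakuchi2009
mir-34a	PTEN	Pineau2010
mir-34a	PKC	Christoffersen2010
mir-34a	PDPK1	Pineau2010
mir-34a	MYC	Christoffersen2010
mir-34a	CDKN1	Sun2008
mir-34a	ELK1	Christoffersen2010
mir-TRDD	TARBP2	Cummins2006
mir-TRDD	RNASEN	Cummins2006
mir-TRDD	DICER1	Cummins2006
mir-TRDD	DGCR8	Ye2008
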