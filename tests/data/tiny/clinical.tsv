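patient_id	age	gender	localisation	grade	ajcc	pT	pN	M	msi	braf	kras	nras
P000	65	female	left	2	II	pT3	pN0	M0	MSS	wt	NA	NA
P001	87	male	rectosigmoideum	2	I	pT4	pN0	M1	NA	wt	NA	wt
P002	81	female	rectum	2	III	pT3	pN1	M0	MSI	NA	NA	NA
P003	81	female	right	2	II	pT3	pN0	M0	MSS	NA	NA	wt
P004	74	male	transverse	2	II	pT3	pN1	M1	NA	wt	NA	mut
P005	75	male	rectosigmoideum	2	II	pT3	pN1	M1	MSI	wt	NA	wt
P006	79	male	rectosigmoideum	1	II	pT3	pN1	M0	MSI	mut	NA	NA
P007	52	female	right	2	0	pT3	pN0	M0	MSS	NA	NA	NA
P008	67	female	transverse	2	III	pT3	pN0	M0	MSI	wt	NA	NA
P009	52	male	right	2	I	pT3	pN1	M0	MSS	wt	NA	NA
P010	73	female	rectum	2	0	pT1	pN0	M0	MSI	wt	NA	NA
P011	57	female	right	2	III	pT4	pN2	M0	NA	NA	NA	NA
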