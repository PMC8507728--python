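sample_id	patient_id	sample_type
P000_T	P000	tumour
P000_VN	P000	normal
P000_S	P000	stool
P001_T	P001	tumour
P001_VN	P001	normal
P001_S	P001	stool
P002_T	P002	tumour
P002_VN	P002	normal
P002_S	P002	stool
P003_T	P003	tumour
P003_VN	P003	normal
P003_S	P003	stool
P004_T	P004	tumour
P004_VN	P004	normal
P004_S	P004	stool
P005_T	P005	tumour
P005_VN	P005	normal
P005_S	P005	stool
P006_T	P006	tumour
P006_VN	P006	normal
P006_S	P006	stool
P007_T	P007	tumour
P007_VN	P007	normal
P007_S	P007	stool
P008_T	P008	tumour
P008_VN	P008	normal
P008_S	P008	stool
P009_T	P009	tumour
P009_VN	P009	normal
P009_S	P009	stool
P010_T	P010	tumour
P010_VN	P010	normal
P010_S	P010	stool
P011_T	P011	tumour
P011_VN	P011	normal
P011_S	P011	stool
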