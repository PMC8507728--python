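patient_id	subtype
P000	2
P001	1
P002	2
P003	2
P004	2
P005	1
P006	2
P007	0
P008	1
P009	0
P010	1
P011	0
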