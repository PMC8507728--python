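genus_id	category	origin	signature_subtype	grade_slope_planted	interaction_planted
g0000	mucosa	oral	-1	False	False
g0001	mucosa	oral	-1	False	False
g0002	mucosa	gut	-1	False	False
g0003	mucosa	oral	-1	False	False
g0004	mucosa	gut	-1	False	False
g0005	mucosa	gut	-1	False	False
g0006	tumour_specific	oral	0	False	False
g0007	tumour_specific	oral	0	False	False
g0008	tumour_specific	oral	1	False	False
g0009	tumour_specific	gut	1	False	False
g0010	tumour_specific	gut	2	False	False
g0011	tumour_specific	gut	2	False	False
g0012	stool	gut	-1	False	False
g0013	stool	gut	-1	False	False
g0014	stool	gut	-1	False	False
g0015	stool	gut	-1	False	False
g0016	stool	gut	-1	False	False
g0017	stool	gut	-1	False	False
g0018	no_difference	gut	-1	False	False
g0019	no_difference	gut	-1	False	False
g0020	no_difference	gut	-1	False	False
g0021	no_difference	gut	-1	False	False
g0022	no_difference	gut	-1	False	False
g0023	no_difference	gut	-1	False	False
g0024	no_difference	gut	-1	False	False
g0025	no_difference	gut	-1	False	False
g0026	no_difference	gut	-1	False	False
g0027	no_difference	gut	-1	False	False
g0028	no_difference	gut	-1	False	False
g0029	no_difference	gut	-1	False	False
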