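genus_id	origin
g0000	oral
g0001	oral
g0002	gut
g0003	oral
g0004	gut
g0005	gut
g0006	oral
g0007	oral
g0008	oral
g0009	gut
g0010	gut
g0011	gut
g0012	gut
g0013	gut
g0014	gut
g0015	gut
g0016	gut
g0017	gut
g0018	gut
g0019	gut
g0020	gut
g0021	gut
g0022	gut
g0023	gut
g0024	gut
g0025	gut
g0026	gut
g0027	gut
g0028	gut
g0029	gut
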