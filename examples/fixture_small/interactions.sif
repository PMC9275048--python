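G0001	background	G0035
G0001	background	G0036
G0002	background	G0009
G0002	background	G0017
G0002	background	G0018
G0002	background	G0039
G0003	background	G0017
G0003	background	G0024
G0003	background	G0028
G0004	background	G0022
G0004	background	G0023
G0005	background	G0010
G0005	background	G0027
G0005	background	G0029
G0005	background	G0038
G0006	background	G0009
G0006	background	G0016
G0006	background	G0024
G0007	background	G0021
G0007	background	G0030
G0007	background	G0034
G0008	background	G0027
G0008	background	G0038
G0009	background	G0036
G0011	background	G0022
G0011	planted	G0024
G0012	background	G0015
G0012	background	G0039
G0014	background	G0024
G0014	background	G0034
G0014	background	G0039
G0016	background	G0036
G0017	background	G0039
G0018	background	G0026
G0022	background	G0023
G0023	background	G0039
G0024	background	G0027
G0026	planted	G0040
G0028	background	G0035
G0028	background	G0040
G0029	planted	G0031
G0029	background	G0032
G0032	planted	G0033
G0033	background	G0037
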