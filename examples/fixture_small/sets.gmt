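planted_module	genes of planted edges	G0011	G0024	G0026	G0029	G0031	G0032	G0033	G0040
random_set_1	decoy	G0004	G0006	G0007	G0020	G0021	G0023	G0024	G0026	G0033	G0035
random_set_2	decoy	G0003	G0007	G0011	G0014	G0020	G0021	G0027	G0030	G0031	G0033
random_set_3	decoy	G0001	G0002	G0006	G0019	G0020	G0028	G0030	G0031	G0033	G0034
random_set_4	decoy	G0003	G0006	G0010	G0011	G0014	G0016	G0018	G0022	G0024	G0038
random_set_5	decoy	G0012	G0013	G0016	G0018	G0024	G0028	G0029	G0030	G0031	G0033
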