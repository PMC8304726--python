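feature_id	layer	rank_sum_score	raw_p	adjusted_p	direction
alpha_f0006	alpha	0.3	0.0046977	0.046977	1
alpha_f0024	alpha	0.266667	0.00499812	0.0499812	-1
alpha_f0031	alpha	0.266667	0.00499812	0.0499812	1
alpha_f0020	alpha	0.233333	0.00499812	0.0499812	-1
alpha_f0005	alpha	0.2	0.0021645	0.021645	1
alpha_f0016	alpha	0.2	0.0021645	0.021645	-1
alpha_f0021	alpha	0.2	0.0046977	0.046977	-1
alpha_f0025	alpha	0.2	0.00499812	0.0499812	1
beta_f0028	beta	0.266667	0.00499812	0.0499812	-1
beta_f0009	beta	0.233333	0.00499812	0.0499812	1
beta_f0020	beta	0.233333	0.00499812	0.0499812	-1
beta_f0022	beta	0.2	0.00499812	0.0499812	-1
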