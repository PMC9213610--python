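species	tissue	n_samples	mean_age_years	min_age_years	max_age_years
Opossum	Ear	45	0.771	0.0384	2.22
Opossum	Liver	48	0.922	0.0384	3.27
Opossum	Tail	7	0.164	0.0384	0.288
Eastern grey kangaroo	Blood	12	4.517	1.820	13.300
Red kangaroo	Blood	37	7.097	0.620	11.730
Red-necked wallaby	Blood	5	7.584	2.020	9.650
Tasmanian devil	Ear	41	3.427	0.500	8.000
Western grey kangaroo	Blood	5	2.708	1.666	5.036
Mouse	Blood	97	0.998	0.0192	2.250
Mouse	Ear	18	0.0671	0.0192	0.115
Mouse	Liver	498	0.0367	0.0191	2.778
Mouse	Muscle	18	0.0671	0.0192	0.115
Mouse	Tail	18	0.0671	0.0192	0.115
Mouse	Whole Brain	18	0.0671	0.0192	0.115
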