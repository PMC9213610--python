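species	max_lifespan_years
Opossum	4.2
Human	122.5
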