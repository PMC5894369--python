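country,elasticity
India,-0.34
Indonesia,-0.43
Bangladesh,-0.49
Philippines,-0.87
Vietnam,-0.53
Armenia,-0.40
China,-0.51
Mexico,-0.55
Turkey,-0.41
Brazil,-0.48
Colombia,-0.44
Thailand,-0.39
Chile,-0.45
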