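energy_kev,interaction_prob,photopeak_fraction
150,0.95,0.75
200,0.92,0.65
284,0.85,0.52
364,0.78,0.45
511,0.65,0.34
637,0.57,0.28
723,0.53,0.25
900,0.47,0.20
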