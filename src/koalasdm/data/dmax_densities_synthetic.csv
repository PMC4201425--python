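source_label,density_ha
synthetic_source_01,0.33
synthetic_source_02,0.5
synthetic_source_03,0.6
synthetic_source_04,0.9
synthetic_source_05,1.3
synthetic_source_06,1.6
synthetic_source_07,2.2
synthetic_source_08,2.9
synthetic_source_09,3.8
synthetic_source_10,11.0
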