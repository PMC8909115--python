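material,density_kg_m3
Flour,1440
PVC,1410
Glass beads,2420
Quartz sand,2650
Steel,7850
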