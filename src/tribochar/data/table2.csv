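mesh_label,d43_um,d43_sd,protein_wt_pct,protein_sd,qm_nc_per_g,qm_sd
No. 60,380.9,9.9,21.7,0.9,157.9,27.8
No. 80,252.7,1.5,23.3,0.2,231.2,74.9
No. 100,192.7,0.5,23.8,0.7,314.5,71.6
No. 140,138.9,0.1,25.4,0.7,323.8,69.1
No. 200,86.3,0.1,25.2,0.4,307.8,78.3
No. 270,61.7,0.0,26.4,0.8,608.8,151.3
Pan (<53 μm),25.0,0.0,14.2,0.1,138.2,49.5
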