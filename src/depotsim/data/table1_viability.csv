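exposure_h,0 mM,0.01 mM,0.1 mM,0.5 mM,1 mM
24,100 ± 4%,86 ± 3%,70 ± 3%,64 ± 0%,43 ± 2%
48,100 ± 4%,105 ± 4%,90 ± 2%,62 ± 35,38 ± 4%
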