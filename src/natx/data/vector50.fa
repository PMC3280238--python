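>mockvec50 bundled 50-nt cloning-vector stub used for contamination masking
GTTAGCTCACTCATTAGGCACCCCAGGCTTTACACTTTATGCTTCCGGCT
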