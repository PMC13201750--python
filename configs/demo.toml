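# Demonstration run: small synthetic cohort at a coarser atlas resolution
# so the full pipeline finishes in about a minute.
seed = 0
n_leads = 120
voxel_size_mm = 0.4
gpc_restarts = 1
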