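name,value
reco_ratio_pct,151
gpp_ratio_pct,86
ch4_equiv_share_open_pct,57
ch4_equiv_share_tree_pct,71
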