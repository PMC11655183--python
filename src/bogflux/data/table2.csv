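site,microform,reco,share_reco,gpp,share_gpp,nee,water_level
open,hollow,296.8,36.3,-464.8,43,-168.1,-0.03
open,hummock,521.1,63.7,-615.4,57,-94.3,-0.13
tree,nT_hollow,155.3,12.7,-124.8,10,30.5,-0.12
tree,T_hollow,170.2,13.9,-112.5,9,57.7,-0.1
tree,nT_hummock,355.7,29.1,-186,14.9,169.6,-0.23
tree,T_hummock,401.1,32.9,-179.6,14.4,221.5,-0.27
tree,branch,140.7,11.5,-648,51.8,-507.3,
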