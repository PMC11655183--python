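site,gpp,reco,nee,nee_sd,ch4,ch4_sd,carbon,carbon_sd,ghg,ghg_sd
open,-1080.3,809.9,-262.4,7.8,36.1,3.4,-226.3,8.5,3.38,1.3
tree,-1250.9,1222.8,-28,5.1,7.1,1.5,-20.9,5.3,1.53,0.6
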