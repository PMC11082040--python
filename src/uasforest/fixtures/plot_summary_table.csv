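plot,treatment,qmd_cm_sm,qmd_cm_uas,tph_sm,tph_uas,tph_gt5_sm,tph_gt5_uas,ba_m2ha_sm,ba_m2ha_uas,cover_pct_sm,cover_pct_uas
SGR-1,SGR,16.2,17.2,307,195,84,78,6.4,4.5,12.8,10.4
SGR-2,SGR,11.2,15.5,658,362,151,146,6.5,6.9,12.6,12.9
FS-Off-1,FS-Off,23.7,18.2,251,387,206,221,11.1,10.1,17.8,21.7
FS-Off-2,FS-Off,24.0,19.4,254,420,168,196,11.5,12.5,22.8,21.5
FS-Off-3,FS-Off,22.4,20.9,263,323,225,239,10.3,11.0,15.7,19.2
FS-On-1,FS-On,23.8,17.6,244,516,158,193,10.8,12.6,22.0,23.1
FS-On-2,FS-On,20.3,17.1,348,540,288,284,11.3,12.3,20.3,28.7
FS-On-3,FS-On,18.9,16.3,225,321,70,71,6.3,6.7,12.2,13.5
CT-1,CT,28.4,26.0,171,196,158,163,10.9,10.4,24.1,19.0
CT-2,CT,33.4,32.5,159,167,149,156,13.9,13.9,26.8,27.5
CT-3,CT,28.2,22.0,189,222,179,202,11.8,8.4,24.7,24.6
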