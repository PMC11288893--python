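residue_type,ss_class,mean_ca,sd_ca,mean_cb,sd_cb
THR,helix,65.5,1.3,68.5,1.3
THR,sheet,61.4,1.5,70.8,1.5
THR,coil,62.0,1.4,69.6,1.3
SER,helix,61.0,1.0,62.9,0.8
SER,sheet,57.5,1.3,64.7,1.2
SER,coil,58.5,1.1,63.9,0.9
ALA,helix,54.9,1.1,18.2,1.0
ALA,sheet,50.6,1.2,20.8,1.5
ALA,coil,52.5,1.1,19.1,1.1
GLY,helix,46.9,1.0,,
GLY,sheet,44.9,1.2,,
GLY,coil,45.3,1.0,,
TYR,helix,60.8,1.3,38.5,1.3
TYR,sheet,56.9,1.5,41.5,1.8
TYR,coil,57.9,1.4,39.5,1.5
GLN,helix,58.6,1.0,28.3,1.0
GLN,sheet,54.6,1.3,31.6,1.7
GLN,coil,55.8,1.1,29.9,1.3
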