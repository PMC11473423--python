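name	tissue_class	frontolimbic
bankssts	cortical	0
caudalanteriorcingulate	cortical	1
caudalmiddlefrontal	cortical	0
cuneus	cortical	0
entorhinal	cortical	0
fusiform	cortical	1
inferiorparietal	cortical	1
inferiortemporal	cortical	0
isthmuscingulate	cortical	0
lateraloccipital	cortical	0
lateralorbitofrontal	cortical	1
lingual	cortical	0
medialorbitofrontal	cortical	1
middletemporal	cortical	0
parahippocampal	cortical	0
paracentral	cortical	0
parsopercularis	cortical	0
parsorbitalis	cortical	0
parstriangularis	cortical	0
pericalcarine	cortical	0
postcentral	cortical	0
posteriorcingulate	cortical	1
precentral	cortical	0
precuneus	cortical	0
rostralanteriorcingulate	cortical	1
rostralmiddlefrontal	cortical	0
superiorfrontal	cortical	0
superiorparietal	cortical	0
superiortemporal	cortical	1
supramarginal	cortical	0
frontalpole	cortical	0
temporalpole	cortical	0
transversetemporal	cortical	0
insula	cortical	0
thalamus	subcortical	1
amygdala	subcortical	1
hippocampus	subcortical	1
mean_thickness	summary	0
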