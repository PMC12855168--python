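# Carbon sources on which the salt-tolerant strains retain high metabolic
# activity in the presence of 300 mM NaCl (PM1/PM2 well compounds).
L-arabinose
D-galactose
N-acetyl-D-glucosamine
Gentiobiose
D-trehalose
D-mannose
D-mannitol
D-arabitol
beta-methyl-D-xyloside
D-melibiose
Maltotriose
Turanose
alpha-D-glucose
Sucrose
L-rhamnose
Maltose
L-fucose
D-cellobiose
Adonitol
alpha-methyl-D-galactoside
beta-methyl-D-glucoside
m-inositol
D-arabinose
D-tagatose
Melibionic acid
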