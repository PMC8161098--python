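property	group	letters
hydrophobicity	polar	RKEDQN
hydrophobicity	neutral	GASTPHY
hydrophobicity	hydrophobic	CLVIMFW
vdw_volume	small	GASTPDC
vdw_volume	medium	NVEQIL
vdw_volume	large	MHKFRYW
polarity	low	LIFWCMVY
polarity	medium	PATGS
polarity	high	HQRKNED
polarizability	low	GASDT
polarizability	medium	CPNVEQIL
polarizability	high	KMHFRYW
charge	positive	KR
charge	negative	DE
charge	neutral	ANCQGHILMFPSTWYV
secondary_structure	helix	EALMQKRH
secondary_structure	strand	VIYCWFT
secondary_structure	coil	GNPSD
solvent_accessibility	buried	ALFCGIVW
solvent_accessibility	exposed	RKQEND
solvent_accessibility	intermediate	MSPTHY
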