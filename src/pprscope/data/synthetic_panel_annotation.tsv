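ref_id	family	is_ppr	tuning_site	helix_cf_start	helix_cf_end	lambda_max_nm	domain	taxon	supergroup
AAG10475.1	PR	1	105	84	209	525	prokaryote	uncultured SAR86 cluster bacterium	Proteobacteria
AAK30179.1	PR	1	105	84	209	490	prokaryote	uncultured marine bacterium HOT75m4	Proteobacteria
BAN14807.1	PR	1	105	84	209	525	prokaryote	Flavobacteriaceae bacterium	Bacteroidetes
AAZ21446.1	PR	1	105	84	209	490	prokaryote	Candidatus Pelagibacter ubique	Proteobacteria
SYNPR001	PR	1	105	84	209	525	eukaryote	Karlodinium micrum	Dinophyceae
SYNPR002	PR	1	105	84	209	525	eukaryote	Ceratium fusus	Dinophyceae
SYNPR003	PR	1	105	84	209	525	eukaryote	Alexandrium andersonii	Dinophyceae
SYNPR004	PR	1	105	84	209	490	eukaryote	Prorocentrum shikokuense	Dinophyceae
AIN36550.1	XR	1		84	209		prokaryote	Salinibacter ruber	Bacteroidetes
ADY17811.1	XR	1		84	209		prokaryote	Octadecabacter arcticus	Proteobacteria
ADY17809.1	XR	1		84	209		prokaryote	Octadecabacter antarcticus	Proteobacteria
ADY17808.1	XR	1		84	209		prokaryote	Octadecabacter sp.	Proteobacteria
ABV22426.1	XR	1		84	209		prokaryote	uncultured marine bacterium	Other_Bacteria
ABV22432.1	XR	1		84	209		prokaryote	uncultured marine bacterium	Other_Bacteria
AAO14677.1	XR	1		84	209		prokaryote	Gloeobacter-like bacterium	Other_Bacteria
AEF32711.1	XR	1		84	209		prokaryote	Marivirga tractuosa	Bacteroidetes
ABV22427.1	XR	1		84	209		prokaryote	uncultured marine bacterium	Other_Bacteria
ADY17806.1	XR	1		84	209		prokaryote	Octadecabacter sp.	Proteobacteria
AJA37445.1	XR	1		84	209		prokaryote	Nonlabens dokdonensis	Bacteroidetes
WP_011404249.1	XR	1		84	209		prokaryote	Salinibacter ruber M31	Bacteroidetes
AEP68177.1	XR	1		84	209		prokaryote	Leeuwenhoekiella blandensis	Bacteroidetes
AKG94905.1	XR	1		84	209		prokaryote	Winogradskyella sp.	Bacteroidetes
BAC88139.1	GR	1		84	209		prokaryote	Gloeobacter violaceus	Other_Bacteria
SYNBR001	BR	1		84	209		prokaryote	Halobacterium salinarum	Other_Bacteria
SYNSRI001	SRI	0		84	209		prokaryote	Halobacterium salinarum	Other_Bacteria
SYNACTR001	ActR	1		84	209		prokaryote	actinobacterium MWH-Uga1	Other_Bacteria
SYNESR001	ESR	1		84	209		prokaryote	Exiguobacterium sibiricum	Other_Bacteria
SYNVIR001	other_rhodopsin	0		84	209		virus	Phaeocystis globosa virus	Virus
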