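curie	label	parents
ENVO:00000428	biome
ENVO:01000020	estuarine biome	ENVO:00000428
ENVO:01000252	freshwater lake biome	ENVO:00000428
ENVO:01000253	freshwater river biome	ENVO:00000428
ENVO:00000447	marine biome	ENVO:00000428
ENVO:00002297	environmental feature
ENVO:00000032	bay	ENVO:00002297
ENVO:00000021	freshwater lake	ENVO:00002297
ENVO:01000326	deep chlorophyll maximum layer	ENVO:00002297
ENVO:00000213	marine mesopelagic zone	ENVO:00002297
ENVO:01001581	sea surface layer	ENVO:00002297
ENVO:00010483	environmental material
ENVO:00002006	liquid water	ENVO:00010483
ENVO:01000238	polar	TEMP:0000020
ENVO:01000206	temperate	TEMP:0000020
ENVO:01000204	tropical	TEMP:0000020
ENVO:09200014	temperature of water	TEMP:0000021
ENVO:3100011	concentration of dioxygen in liquid water	TEMP:0000022
ENVO:3100022	concentration of nitrate in liquid water	TEMP:0000022
ENVO:3100036	concentration of chlorophyll in liquid water	TEMP:0000022
ENVO:3100008	concentration of chlorophyll a in liquid water	ENVO:3100036
PMO:00000076	latitude coordinate measurement datum start	TEMP:0000021
PMO:00000079	latitude coordinate measurement datum stop	TEMP:0000021
UO:0000000	unit
UO:0000051	concentration unit	UO:0000000
UO:0000062	molar	UO:0000051
UO:0000063	millimolar	UO:0000051
UO:0000064	micromolar	UO:0000051
UO:0000065	nanomolar	UO:0000051
UO:0010004	micromole per kilogram	UO:0000051
UO:0000005	temperature unit	UO:0000000
UO:0000027	degree Celsius	UO:0000005
UO:0000012	kelvin	UO:0000005
UO:0000185	degree	UO:0000000
UO:0000008	meter	UO:0000000
OBI:0000968	device
OBI:0001057	high performance liquid chromatography instrument	OBI:0000968
OBI:0400044	flow cytometer	OBI:0000968
OBI:0400143	fluorometer	OBI:0000968
OBI:0400169	microscope	OBI:0000968
OBI:0400115	spectrophotometer	OBI:0000968
PATO:0000001	quality
PATO:0000033	concentration of	PATO:0000001
CHEBI:24431	chemical entity
CHEBI:28966	chlorophyll	CHEBI:24431
CHEBI:18230	chlorophyll a	CHEBI:28966
CHEBI:17632	nitrate	CHEBI:24431
CHEBI:18367	phosphate	CHEBI:24431
CHEBI:15379	dioxygen	CHEBI:24431
CHEBI:26675	silicic acid	CHEBI:24431
TEMP:0000001	concentration of phosphate in liquid water	TEMP:0000022
TEMP:0000002	concentration of silicic acid in liquid water	TEMP:0000022
TEMP:0000010	sample identifier datum	TEMP:0000021
TEMP:0000011	longitude coordinate measurement datum	TEMP:0000021
TEMP:0000012	collection datetime datum	TEMP:0000021
TEMP:0000013	satellite navigation receiver	OBI:0000968
TEMP:0000014	conductivity-temperature-depth sensor	OBI:0000968
TEMP:0000020	climate zone
TEMP:0000021	environmental measurement datum
TEMP:0000022	concentration of chemical entity in environmental material	TEMP:0000021
TEMP:0000023	depth of water datum	TEMP:0000021
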