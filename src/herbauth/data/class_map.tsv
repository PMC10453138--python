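# Default oregano class map: taxa reported by metabarcoding of commercial
# oregano and their role in the authentication scheme.
# ingredient = declared species; adulterant = bulking species reported in the
# fraud literature; contaminant = field weeds / co-processed foodstuffs;
# noise = rare or geographically implausible attributions.
# Entries ending in "spp." act as genus wildcards.
taxon	class_label
Origanum majorana	adulterant
Origanum onites	ingredient
Origanum vulgare	ingredient
Origanum spp.	ingredient
Aloysia spp.	noise
Alyssum spp.	contaminant
Amaranthus spp.	contaminant
Aniba hostmanniana	noise
Anisosciadium spp.	noise
Anisosciadium lanatum	noise
Arbutus spp.	contaminant
Artemisia spp.	contaminant
Atriplex spp.	contaminant
Avena spp.	contaminant
Bidens spp.	contaminant
Brassica spp.	contaminant
Calycolpus spp.	noise
Calycolpus moritzianus	noise
Calystegia sepium	contaminant
Camelina spp.	contaminant
Camonea spp.	contaminant
Camonea umbrellata	contaminant
Carpinus viminea	noise
Carthamus tinctorius	contaminant
Chenopodium album	contaminant
Chenopodium spp.	contaminant
Chionanthus spp.	noise
Cicer arietinum	contaminant
Cinnamomum spp.	contaminant
Cistus spp.	adulterant
Convolvulus arvensis	contaminant
Convolvulus spp.	contaminant
Conyza spp.	contaminant
Corylus spp.	contaminant
Cuminum cyminum	contaminant
Cuscuta spp.	noise
Cuscuta japonica	noise
Daucus spp.	contaminant
Descurainia sophia	contaminant
Descurainia stricta	contaminant
Ephedra alata	noise
Erigeron spp.	noise
Erysimum spp.	noise
Erysimum teretifolium	noise
Fraxinus spp.	noise
Galinsoga parviflora	contaminant
Helianthemum spp.	contaminant
Hypericum spp.	contaminant
Ipomea spp.	contaminant
Laurus nobilis	contaminant
Malva spp.	contaminant
Malva parviflora	contaminant
Medicago sativa	contaminant
Medicago spp.	contaminant
Melilotus albus	contaminant
Melilotus officinalis	contaminant
Melilotus spp.	contaminant
Mentha x piperita	contaminant
Mentheae (tribe)	contaminant
Myrcia sylvatica	noise
Myrtus communis	adulterant
Nama undulata	noise
Neuontobotrys tarapacana	noise
Olea europaea	adulterant
Panax stipuleanatus	noise
Perilla spp.	noise
Petroselinum crispum	contaminant
Plantago spp.	contaminant
Raphanus sativus	contaminant
Reseda lutea	contaminant
Rhodamnia argentea	noise
Rhodostemonodaphne rufovirgata	noise
Salvia spp.	noise
Saposhnikovia divaricata	noise
Satureja spp.	contaminant
Sinocrassula yunnanensis	noise
Solanum spp.	contaminant
Sonchus asper	contaminant
Sonchus spp.	contaminant
Syringa spp.	noise
Syringa wolfii	noise
Tessaria spp.	noise
Thymus spp.	contaminant
Thymus vulgaris	contaminant
Thymus marschallianus	contaminant
Trifolium spp.	contaminant
Trigonella spp.	contaminant
Valerianella spp.	contaminant
Vicia narbonensis	contaminant
Vicia sativa	contaminant
Vicia spp.	contaminant
# Aliases for reported-name variants (abbreviations and slash-composites as
# they appear in attribution-pipeline output) and sumac, a bulking species
# reported in the adulteration literature.
O. majorana	adulterant
Camonea/Ipomoea spp.	contaminant
Salvia/perilla spp.	noise
Calystegia spp.	contaminant
Rhus coriaria	adulterant
Rhus spp.	adulterant
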