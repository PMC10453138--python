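# Metabarcoding read counts attributed in the ESA oregano quality-control
# material (a gravimetric reference blend of nine botanicals).  Sumac is
# declared at 10% mass but yielded zero reads (DNA extraction dropout);
# bindweed (Convolvulus) is declared at 1% mass but dominates the reads.
sample	taxon	kingdom	reads
esa_qc	Origanum vulgare	Plantae	1126
esa_qc	Origanum onites	Plantae	109
esa_qc	Origanum spp.	Plantae	564
esa_qc	Thymus spp.	Plantae	345
esa_qc	Convolvulus spp.	Plantae	3771
esa_qc	Cistus spp.	Plantae	606
esa_qc	Myrtus communis	Plantae	25
esa_qc	Olea europaea	Plantae	33
esa_qc	Corylus spp.	Plantae	531
esa_qc	Rhus coriaria	Plantae	0
esa_qc	Amaranthus spp.	Plantae	1105
esa_qc	Camonea/Ipomoea spp.	Plantae	505
esa_qc	Calystegia spp.	Plantae	2974
esa_qc	Chenopodium spp.	Plantae	1306
esa_qc	O. majorana	Plantae	4
esa_qc	Mentha x piperita	Plantae	133
esa_qc	Salvia/perilla spp.	Plantae	133
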