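# Declared gravimetric composition of the ESA oregano quality-control
# material (mass fractions sum to 1).
species	mass_fraction
Origanum vulgare	0.22
Origanum onites	0.22
Olea europaea	0.10
Myrtus communis	0.10
Cistus incanus	0.10
Rhus coriaria	0.10
Corylus avellana	0.10
Thymus vulgaris	0.05
Convolvulus arvensis	0.01
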