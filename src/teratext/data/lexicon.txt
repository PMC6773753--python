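chd
club foot
down syndrome
dwarfism
gastroschisis
hydrocephalus
microcephaly
trisomy 18
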