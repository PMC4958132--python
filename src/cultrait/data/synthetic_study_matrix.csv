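taxon,animism,afterlife,shamanism,ancestor_worship,high_gods
Hadza,1,0,0,1,2
Sandawe,1,1,0,1,2
Kung,1,1,1,1,1
Gwi,1,1,1,1,2
Mbuti,1,0,0,1,1
Aka,1,0,0,1,1
Vedda,1,1,1,2,1
Andamanese,1,1,1,2,1
Tiwi,1,1,1,1,2
Aranda,1,1,1,2,2
Walbiri,1,1,1,1,2
Semang,1,1,1,2,2
Agta,1,1,1,2,3
Badjau,1,1,1,1,2
Ainu,1,1,1,4,1
Gilyak,1,1,1,3,1
Yukaghir,1,1,1,3,1
Aleut,1,1,1,4,1
CopperEskimo,1,1,1,4,1
Slave,1,0,1,1,1
Kaska,1,1,1,1,1
Eyak,1,1,1,1,1
Twana,1,1,1,4,1
Yurok,1,1,1,3,1
Montagnais,1,1,1,3,1
GrosVentre,1,1,1,1,4
Comanche,1,1,1,1,3
Seri,1,1,1,1,3
Warao,1,1,1,2,4
Yahgan,1,1,1,2,1
Siriono,1,0,0,1,1
Botocudo,1,0,0,1,1
Aweikoma,1,0,0,1,1
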