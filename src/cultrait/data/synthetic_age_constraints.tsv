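clade_id	date_set	min_age_kya	leaf_set
root_all	shallow	100	Outgroup,Hadza,Sandawe,Kung,Gwi,Mbuti,Aka,Vedda,Andamanese,Tiwi,Aranda,Walbiri,Semang,Agta,Badjau,Ainu,Gilyak,Yukaghir,Aleut,CopperEskimo,Slave,Kaska,Eyak,Twana,Yurok,Montagnais,GrosVentre,Comanche,Seri,Warao,Yahgan,Siriono,Botocudo,Aweikoma
hg_lca	shallow	65	Hadza,Sandawe,Kung,Gwi,Mbuti,Aka,Vedda,Andamanese,Tiwi,Aranda,Walbiri,Semang,Agta,Badjau,Ainu,Gilyak,Yukaghir,Aleut,CopperEskimo,Slave,Kaska,Eyak,Twana,Yurok,Montagnais,GrosVentre,Comanche,Seri,Warao,Yahgan,Siriono,Botocudo,Aweikoma
out_of_africa	shallow	60	Vedda,Andamanese,Tiwi,Aranda,Walbiri,Semang,Agta,Badjau,Ainu,Gilyak,Yukaghir,Aleut,CopperEskimo,Slave,Kaska,Eyak,Twana,Yurok,Montagnais,GrosVentre,Comanche,Seri,Warao,Yahgan,Siriono,Botocudo,Aweikoma
african	shallow	40	Hadza,Sandawe,Kung,Gwi,Mbuti,Aka
khoisan_pygmy	shallow	30	Kung,Gwi,Mbuti,Aka
australia	shallow	45	Tiwi,Aranda,Walbiri
east_asia	shallow	35	Semang,Agta,Badjau,Ainu,Gilyak,Yukaghir
beringia_america	shallow	20	Aleut,CopperEskimo,Slave,Kaska,Eyak,Twana,Yurok,Montagnais,GrosVentre,Comanche,Seri,Warao,Yahgan,Siriono,Botocudo,Aweikoma
amerind	shallow	14	Twana,Yurok,Montagnais,GrosVentre,Comanche,Seri,Warao,Yahgan,Siriono,Botocudo,Aweikoma
root_all	deep	180	Outgroup,Hadza,Sandawe,Kung,Gwi,Mbuti,Aka,Vedda,Andamanese,Tiwi,Aranda,Walbiri,Semang,Agta,Badjau,Ainu,Gilyak,Yukaghir,Aleut,CopperEskimo,Slave,Kaska,Eyak,Twana,Yurok,Montagnais,GrosVentre,Comanche,Seri,Warao,Yahgan,Siriono,Botocudo,Aweikoma
hg_lca	deep	120	Hadza,Sandawe,Kung,Gwi,Mbuti,Aka,Vedda,Andamanese,Tiwi,Aranda,Walbiri,Semang,Agta,Badjau,Ainu,Gilyak,Yukaghir,Aleut,CopperEskimo,Slave,Kaska,Eyak,Twana,Yurok,Montagnais,GrosVentre,Comanche,Seri,Warao,Yahgan,Siriono,Botocudo,Aweikoma
out_of_africa	deep	75	Vedda,Andamanese,Tiwi,Aranda,Walbiri,Semang,Agta,Badjau,Ainu,Gilyak,Yukaghir,Aleut,CopperEskimo,Slave,Kaska,Eyak,Twana,Yurok,Montagnais,GrosVentre,Comanche,Seri,Warao,Yahgan,Siriono,Botocudo,Aweikoma
african	deep	100	Hadza,Sandawe,Kung,Gwi,Mbuti,Aka
khoisan_pygmy	deep	60	Kung,Gwi,Mbuti,Aka
australia	deep	50	Tiwi,Aranda,Walbiri
east_asia	deep	45	Semang,Agta,Badjau,Ainu,Gilyak,Yukaghir
beringia_america	deep	25	Aleut,CopperEskimo,Slave,Kaska,Eyak,Twana,Yurok,Montagnais,GrosVentre,Comanche,Seri,Warao,Yahgan,Siriono,Botocudo,Aweikoma
amerind	deep	18	Twana,Yurok,Montagnais,GrosVentre,Comanche,Seri,Warao,Yahgan,Siriono,Botocudo,Aweikoma
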