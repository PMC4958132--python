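(Outgroup,(((Hadza,Sandawe),((Kung,Gwi),(Mbuti,Aka))),(Vedda,(Andamanese,((Tiwi,(Aranda,Walbiri)),(((Semang,(Agta,Badjau)),(Ainu,(Gilyak,Yukaghir))),(((Aleut,CopperEskimo),(Slave,(Kaska,Eyak))),(((Twana,Yurok),(Montagnais,(GrosVentre,Comanche))),(Seri,((Warao,Yahgan),(Siriono,(Botocudo,Aweikoma))))))))))));
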