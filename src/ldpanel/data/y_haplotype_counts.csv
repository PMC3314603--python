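breed,hap1,hap2,hap3,hap4
Angus,0,0,0,9
Ayrshire,0,0,0,9
Beefmaster,2,0,0,5
Blonde d'Aquitaine,0,9,1,0
Brahman,7,0,0,3
Brown Swiss,0,10,0,0
Charolais,0,11,0,0
Fleckvieh,0,18,0,2
Friesian,0,0,5,12
Gelbvieh,0,4,0,1
Hereford,0,0,0,9
Holstein,0,0,0,15
Jersey,0,0,14,5
Limousin,0,10,0,0
Montbeliard,0,10,0,0
N'Dama,0,2,0,0
Normande,0,0,0,10
Norwegian Red,0,0,0,7
Red Angus,0,0,0,10
Red Dairy (Angler),0,0,0,10
Red Danish,0,0,0,15
Santa Gertrudis,8,0,0,0
All breeds,17,74,20,122
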