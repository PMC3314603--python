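breed,hap1,hap2,hap3,hap4,hap5,hap6,hap7,undetermined
Angus,10,0,0,0,0,0,0,0
Ayrshire,9,0,0,0,1,0,0,0
Beefmaster,7,0,0,0,1,0,0,1
Blonde d'Aquitaine,10,0,0,0,0,0,0,0
Brahman,8,0,0,0,0,0,3,0
Brown Swiss,9,0,0,1,0,0,0,0
Charolais,10,0,0,0,0,0,0,0
Fleckvieh,20,0,0,0,0,0,0,0
Friesian,16,0,0,0,0,0,1,0
Gelbvieh,3,0,0,0,0,0,0,2
Guernsey,10,0,0,0,0,0,0,0
Hereford,9,0,0,0,0,0,1,0
Holstein,16,0,0,0,0,0,2,0
Jersey,21,0,0,0,0,1,5,1
Limousin,10,0,0,0,0,0,0,0
Montbeliard,10,0,0,0,0,0,0,0
N'Dama,10,0,0,0,0,0,0,0
Normande,9,0,0,0,1,0,0,0
Norwegian Red,6,0,0,0,1,0,0,4
Red Angus,9,1,0,0,0,0,0,0
Red Dairy (Angler),10,0,0,0,0,0,0,0
Red Danish,28,0,1,1,1,0,0,0
Santa Gertrudis,9,0,0,0,1,0,0,0
All breeds,259,1,1,2,6,1,12,8
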