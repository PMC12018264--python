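crop_id,crop_name,food_crop,crop_group
whea,wheat,1,cereals
rice,rice,1,cereals
maiz,maize,1,cereals
barl,barley,1,cereals
pmil,pearl millet,1,cereals
smil,small millet,1,cereals
sorg,sorghum,1,cereals
bean,bean,1,pulses
chic,chickpea,1,pulses
cowp,cowpea,1,pulses
pige,pigeon pea,1,pulses
lent,lentil,1,pulses
opul,other pulses,1,pulses
pota,potato,1,starchy roots
swpo,sweet potato,1,starchy roots
yams,yams,1,starchy roots
cass,cassava,1,starchy roots
soyb,soybean,1,oil crops
grou,groundnut,1,oil crops
cnut,coconut,1,oil crops
oilp,oil palm,1,oil crops
sunf,sunflower,1,oil crops
rape,rapeseed,1,oil crops
sesa,sesame seed,1,oil crops
bana,banana,1,fruits and vegetables
plnt,plantain,1,fruits and vegetables
toma,tomato,1,fruits and vegetables
onio,onion,1,fruits and vegetables
citr,citrus,1,fruits and vegetables
vege,vegetables,1,fruits and vegetables
ocer,other cereals,0,
orts,other roots,0,
ooil,other oil crops,0,
sugc,sugarcane,0,
sugb,sugar beet,0,
cott,cotton,0,
ofib,other fibre crops,0,
acof,arabica coffee,0,
rcof,robusta coffee,0,
coco,cocoa,0,
teas,tea,0,
toba,tobacco,0,
trof,tropical fruit,0,
temf,temperate fruit,0,
grap,grapes,0,
rest,rest of crops,0,
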