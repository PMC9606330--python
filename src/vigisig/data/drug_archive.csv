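synonym,ingredient,class,region
bevacizumab,bevacizumab,anti_VEGF_mAb,FDA
avastin,bevacizumab,anti_VEGF_mAb,FDA
mvasi,bevacizumab,anti_VEGF_mAb,FDA
zirabev,bevacizumab,anti_VEGF_mAb,FDA
bevacizumab-awwb,bevacizumab,anti_VEGF_mAb,FDA
ramucirumab,ramucirumab,anti_VEGFR_mAb,FDA
cyramza,ramucirumab,anti_VEGFR_mAb,FDA
IMC-1121B,ramucirumab,anti_VEGFR_mAb,FDA
aflibercept,aflibercept,VEGF_trap,FDA
ziv-aflibercept,aflibercept,VEGF_trap,FDA
zaltrap,aflibercept,VEGF_trap,FDA
eylea,aflibercept,VEGF_trap,FDA
AVE0005,aflibercept,VEGF_trap,FDA
sunitinib,sunitinib,TKI,FDA
sunitinib malate,sunitinib,TKI,FDA
sutent,sunitinib,TKI,FDA
SU11248,sunitinib,TKI,FDA
lenvatinib,lenvatinib,TKI,FDA
lenvatinib mesylate,lenvatinib,TKI,FDA
lenvima,lenvatinib,TKI,FDA
E7080,lenvatinib,TKI,FDA
nintedanib,nintedanib,TKI,FDA
ofev,nintedanib,TKI,FDA
vargatef,nintedanib,TKI,FDA
BIBF1120,nintedanib,TKI,FDA
pazopanib,pazopanib,TKI,FDA
pazopanib hydrochloride,pazopanib,TKI,FDA
votrient,pazopanib,TKI,FDA
GW786034,pazopanib,TKI,FDA
cabozantinib,cabozantinib,TKI,FDA
cabometyx,cabozantinib,TKI,FDA
cometriq,cabozantinib,TKI,FDA
XL184,cabozantinib,TKI,FDA
sorafenib,sorafenib,TKI,FDA
sorafenib tosylate,sorafenib,TKI,FDA
nexavar,sorafenib,TKI,FDA
BAY43-9006,sorafenib,TKI,FDA
axitinib,axitinib,TKI,FDA
inlyta,axitinib,TKI,FDA
AG-013736,axitinib,TKI,FDA
regorafenib,regorafenib,TKI,FDA
stivarga,regorafenib,TKI,FDA
BAY73-4506,regorafenib,TKI,FDA
apatinib,apatinib,TKI,NMPA
apatinib mesylate,apatinib,TKI,NMPA
aitan,apatinib,TKI,NMPA
YN968D1,apatinib,TKI,NMPA
vandetanib,vandetanib,TKI,FDA
caprelsa,vandetanib,TKI,FDA
ZD6474,vandetanib,TKI,FDA
tivozanib,tivozanib,TKI,FDA
fotivda,tivozanib,TKI,FDA
AV-951,tivozanib,TKI,FDA
cediranib,cediranib,TKI,FDA
recentin,cediranib,TKI,FDA
AZD2171,cediranib,TKI,FDA
erdafitinib,erdafitinib,TKI,FDA
balversa,erdafitinib,TKI,FDA
JNJ-42756493,erdafitinib,TKI,FDA
fruquintinib,fruquintinib,TKI,NMPA
elunate,fruquintinib,TKI,NMPA
HMPL-013,fruquintinib,TKI,NMPA
vatalanib,vatalanib,TKI,FDA
PTK787,vatalanib,TKI,FDA
ZK222584,vatalanib,TKI,FDA
anlotinib,anlotinib,TKI,NMPA
anlotinib hydrochloride,anlotinib,TKI,NMPA
AL3818,anlotinib,TKI,NMPA
recombinant human endostatin,recombinant human endostatin,other_antiangiogenic,NMPA
endostar,recombinant human endostatin,other_antiangiogenic,NMPA
rh-endostatin,recombinant human endostatin,other_antiangiogenic,NMPA
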