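name,brand,product_type,route,indication,bundled
Basiliximab,Simulect,mAb,IV,acute,1
Bevacizumab,Avastin,mAb,IV,chronic,0
Cetuximab,Erbitux,mAb,IV,chronic,0
Infliximab,Remicade,mAb,IV,chronic,0
Oftamumab,Arzerra,mAb,IV,chronic,1
Panitumumab,Vectibix,mAb,IV,chronic,0
Tocilizumab,Actemra,mAb,IV,chronic,0
Trastuzumab,Herceptin,mAb,IV,chronic,0
Adalimumab,Humira,mAb,SC,chronic,1
Canakinumab,Ilaris,mAb,SC,chronic,1
Certolizumab pegol,Cimzia,fAb,SC,chronic,1
Denosumab,Prolia,mAb,SC,chronic,1
Etanercept,Enbrel,fusion protein,SC,chronic,1
Golimumab,Simponi,mAb,SC,chronic,1
Omalizumab,Xolair,mAb,SC,chronic,1
Ustekinumab,Stelara,mAb,SC,chronic,1
Palivizumab,Synagis,mAb,IM,acute,1
Interferon beta-1a,Avonex,interferon protein,IM,chronic,1
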