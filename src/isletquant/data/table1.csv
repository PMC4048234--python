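patient_id,group,gender,age,bmi,treatment,source,location,n_islets_tmem27,n_islets_bace2,n_islets_insulin
ND01,ND,M,51,21,no,Surgery,head,10,10,20
ND02,ND,M,56,32,no,Surgery,head,10,3,13
ND03,ND,F,30,28,no,Surgery,tail,7,10,20
ND04,ND,M,54,25,no,Surgery,head,10,10,20
ND05,ND,F,46,31,no,Surgery,tail,10,10,20
ND06,ND,F,49,24,no,Surgery,head,10,10,20
ND07,ND,M,78,29,no,Surgery,head,8,10,12
ND08,ND,M,72,21,no,Autopsy,body,9,10,20
ND09,ND,F,89,25,no,Autopsy,body,10,10,20
ND10,ND,F,81,25,no,Autopsy,body,11,10,20
ND11,ND,F,74,24,no,Autopsy,body,10,8,20
ND12,ND,M,63,28,no,Cadaveric donor,body,9,10,20
ND13,ND,M,78,24,no,Cadaveric donor,body,8,10,14
ND14,ND,M,76,26,no,Cadaveric donor,body,10,10,20
ND15,ND,F,70,29,no,Cadaveric donor,body,5,3,4
ND16,ND,F,62,26,no,Cadaveric donor,body,5,10,15
ND17,ND,F,78,26,no,Cadaveric donor,body,4,10,10
ND18,ND,M,82,28,no,Surgery,head,10,10,9
ND19,ND,F,76,28,no,Surgery,head,9,10,17
ND20,ND,F,55,26,no,Surgery,body,4,10,15
ND21,ND,M,71,24,no,Surgery,head,10,10,10
ND22,ND,M,72,29,no,Surgery,head,10,10,10
ND23,ND,F,57,19,no,Surgery,body,10,10,10
ND24,ND,F,50,23,no,Surgery,head,10,10,10
ND25,ND,F,77,28,no,Surgery,body,7,10,20
ND26,ND,F,61,26,no,Surgery,body,3,10,18
ND27,ND,F,69,29,no,Surgery,body,6,10,15
ND28,ND,M,57,24,no,Surgery,body,7,5,20
T2D01,T2D,F,66,29,Insulin,Surgery,head,10,5,20
T2D02,T2D,F,62,32,Metformin,Surgery,body,12,2,13
T2D03,T2D,M,70,35,Diet,Surgery,head,9,5,20
T2D04,T2D,M,63,31,Metformin,Surgery,head,9,5,20
T2D05,T2D,M,68,33,Metformin,Surgery,tail,6,15,20
T2D06,T2D,F,83,23,Diet,Autopsy,body,10,5,20
T2D07,T2D,M,77,26,Metformin,Autopsy,body,10,10,15
T2D08,T2D,F,74,23,Metformin,Autopsy,body,10,10,12
T2D09,T2D,M,61,28,Insulin,Cadaveric donor,body,11,10,20
T2D10,T2D,M,66,23,Metformin,Cadaveric donor,body,10,10,20
T2D11,T2D,F,53,30,Metformin,Cadaveric donor,body,1,9,20
T2D12,T2D,F,54,24,Metformin,Cadaveric donor,body,10,10,20
T2D13,T2D,F,75,27,Metformin,Cadaveric donor,body,6,10,14
T2D14,T2D,F,62,30,Insulin,Surgery,not specified,10,10,20
T2D15,T2D,F,78,34,Diet,Surgery,not specified,6,6,4
T2D16,T2D,M,79,36,Diet,Surgery,head,6,1,15
T2D17,T2D,M,60,32,Insulin,Surgery,head,10,10,10
T2D18,T2D,M,45,34,Diet,Autopsy,head,10,10,12
T2D19,T2D,F,59,33,Metformin,Autopsy,body,10,10,12
T2D20,T2D,F,74,31,Sulfonylurea,Autopsy,head,10,10,12
T2D21,T2D,M,59,32,Diet,Autopsy,body,10,10,12
T2D22,T2D,M,80,29,Metformin,Autopsy,head,10,10,12
T2D23,T2D,F,54,30,Metformin,Autopsy,head,10,10,12
T2D24,T2D,F,63,32,N/A,Autopsy,head,10,10,12
T2D25,T2D,M,58,31,Metformin,Autopsy,body,10,10,12
T2D26,T2D,M,53,34,Metformin,Autopsy,body,10,10,12
T2D27,T2D,F,55,33,Metformin,Autopsy,body,10,10,12
T2D28,T2D,M,51,36,N/A,Autopsy,head,10,10,12
T2D29,T2D,M,68,28,Sulfonylurea,Autopsy,head,10,9,12
T2D30,T2D,F,54,29,Metformin,Autopsy,body,10,10,12
T2D31,T2D,M,56,31,Metformin,Autopsy,head,10,10,12
T2D32,T2D,M,57,34,Sulfonylurea,Autopsy,body,10,10,12
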