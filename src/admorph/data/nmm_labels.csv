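label_id,structure_name,merged_name,hemisphere,tissue_class,paired_partner,in_features
1,3rdVentricle,3rdVentricle,none,ventricle_csf,,1
2,4thVentricle,4thVentricle,none,ventricle_csf,,1
3,RightAccumbensArea,AccumbensArea,right,deep_gm,LeftAccumbensArea,1
4,LeftAccumbensArea,AccumbensArea,left,deep_gm,RightAccumbensArea,1
5,RightAmygdala,Amygdala,right,deep_gm,LeftAmygdala,1
6,LeftAmygdala,Amygdala,left,deep_gm,RightAmygdala,1
7,BrainStem,BrainStem,none,other,,1
8,RightCaudate,Caudate,right,deep_gm,LeftCaudate,1
9,LeftCaudate,Caudate,left,deep_gm,RightCaudate,1
10,RightCerebellumExterior,CerebellumExterior,right,other,LeftCerebellumExterior,1
11,LeftCerebellumExterior,CerebellumExterior,left,other,RightCerebellumExterior,1
12,RightCerebellumWhiteMatter,CerebellumWhiteMatter,right,wm,LeftCerebellumWhiteMatter,1
13,LeftCerebellumWhiteMatter,CerebellumWhiteMatter,left,wm,RightCerebellumWhiteMatter,1
14,RightCerebralWhiteMatter,CerebralWhiteMatter,right,wm,LeftCerebralWhiteMatter,1
15,LeftCerebralWhiteMatter,CerebralWhiteMatter,left,wm,RightCerebralWhiteMatter,1
16,CSF,CSF,none,other_csf,,1
17,RightHippocampus,Hippocampus,right,deep_gm,LeftHippocampus,1
18,LeftHippocampus,Hippocampus,left,deep_gm,RightHippocampus,1
19,RightInfLatVent,InfLatVent,right,ventricle_csf,LeftInfLatVent,1
20,LeftInfLatVent,InfLatVent,left,ventricle_csf,RightInfLatVent,1
21,RightLateralVentricle,LateralVentricle,right,ventricle_csf,LeftLateralVentricle,1
22,LeftLateralVentricle,LateralVentricle,left,ventricle_csf,RightLateralVentricle,1
23,RightPallidum,Pallidum,right,deep_gm,LeftPallidum,1
24,LeftPallidum,Pallidum,left,deep_gm,RightPallidum,1
25,RightPutamen,Putamen,right,deep_gm,LeftPutamen,1
26,LeftPutamen,Putamen,left,deep_gm,RightPutamen,1
27,RightThalamusProper,ThalamusProper,right,deep_gm,LeftThalamusProper,1
28,LeftThalamusProper,ThalamusProper,left,deep_gm,RightThalamusProper,1
29,RightVentralDC,VentralDC,right,deep_gm,LeftVentralDC,1
30,LeftVentralDC,VentralDC,left,deep_gm,RightVentralDC,1
31,RightBasalForebrain,BasalForebrain,right,deep_gm,LeftBasalForebrain,1
32,LeftBasalForebrain,BasalForebrain,left,deep_gm,RightBasalForebrain,1
33,RightVessel,Vessel,right,other,LeftVessel,0
34,LeftVessel,Vessel,left,other,RightVessel,0
35,OpticChiasm,OpticChiasm,none,other,,0
36,RightCerebralExterior,CerebralExterior,right,other,LeftCerebralExterior,0
37,LeftCerebralExterior,CerebralExterior,left,other,RightCerebralExterior,0
38,CerebellarVermalLobulesI-V,CerebellarVermalLobulesI-V,none,other,,1
39,CerebellarVermalLobulesVI-VII,CerebellarVermalLobulesVI-VII,none,other,,1
40,CerebellarVermalLobulesVIII-X,CerebellarVermalLobulesVIII-X,none,other,,1
101,RightACgG,ACgG,right,cortical_gm,LeftACgG,1
102,LeftACgG,ACgG,left,cortical_gm,RightACgG,1
103,RightAIns,AIns,right,cortical_gm,LeftAIns,1
104,LeftAIns,AIns,left,cortical_gm,RightAIns,1
105,RightAnG,AnG,right,cortical_gm,LeftAnG,1
106,LeftAnG,AnG,left,cortical_gm,RightAnG,1
107,RightAOrG,AOrG,right,cortical_gm,LeftAOrG,1
108,LeftAOrG,AOrG,left,cortical_gm,RightAOrG,1
109,RightCalc,Calc,right,cortical_gm,LeftCalc,1
110,LeftCalc,Calc,left,cortical_gm,RightCalc,1
111,RightCO,CO,right,cortical_gm,LeftCO,1
112,LeftCO,CO,left,cortical_gm,RightCO,1
113,RightCun,Cun,right,cortical_gm,LeftCun,1
114,LeftCun,Cun,left,cortical_gm,RightCun,1
115,RightEntA,EntA,right,cortical_gm,LeftEntA,1
116,LeftEntA,EntA,left,cortical_gm,RightEntA,1
117,RightFO,FO,right,cortical_gm,LeftFO,1
118,LeftFO,FO,left,cortical_gm,RightFO,1
119,RightFRP,FRP,right,cortical_gm,LeftFRP,1
120,LeftFRP,FRP,left,cortical_gm,RightFRP,1
121,RightFuG,FuG,right,cortical_gm,LeftFuG,1
122,LeftFuG,FuG,left,cortical_gm,RightFuG,1
123,RightGRe,GRe,right,cortical_gm,LeftGRe,1
124,LeftGRe,GRe,left,cortical_gm,RightGRe,1
125,RightIOG,IOG,right,cortical_gm,LeftIOG,1
126,LeftIOG,IOG,left,cortical_gm,RightIOG,1
127,RightITG,ITG,right,cortical_gm,LeftITG,1
128,LeftITG,ITG,left,cortical_gm,RightITG,1
129,RightLiG,LiG,right,cortical_gm,LeftLiG,1
130,LeftLiG,LiG,left,cortical_gm,RightLiG,1
131,RightLOrG,LOrG,right,cortical_gm,LeftLOrG,1
132,LeftLOrG,LOrG,left,cortical_gm,RightLOrG,1
133,RightMCgG,MCgG,right,cortical_gm,LeftMCgG,1
134,LeftMCgG,MCgG,left,cortical_gm,RightMCgG,1
135,RightMFC,MFC,right,cortical_gm,LeftMFC,1
136,LeftMFC,MFC,left,cortical_gm,RightMFC,1
137,RightMFG,MFG,right,cortical_gm,LeftMFG,1
138,LeftMFG,MFG,left,cortical_gm,RightMFG,1
139,RightMOG,MOG,right,cortical_gm,LeftMOG,1
140,LeftMOG,MOG,left,cortical_gm,RightMOG,1
141,RightMOrG,MOrG,right,cortical_gm,LeftMOrG,1
142,LeftMOrG,MOrG,left,cortical_gm,RightMOrG,1
143,RightMPoG,MPoG,right,cortical_gm,LeftMPoG,1
144,LeftMPoG,MPoG,left,cortical_gm,RightMPoG,1
145,RightMPrG,MPrG,right,cortical_gm,LeftMPrG,1
146,LeftMPrG,MPrG,left,cortical_gm,RightMPrG,1
147,RightMSFG,MSFG,right,cortical_gm,LeftMSFG,1
148,LeftMSFG,MSFG,left,cortical_gm,RightMSFG,1
149,RightMTG,MTG,right,cortical_gm,LeftMTG,1
150,LeftMTG,MTG,left,cortical_gm,RightMTG,1
151,RightOCP,OCP,right,cortical_gm,LeftOCP,1
152,LeftOCP,OCP,left,cortical_gm,RightOCP,1
153,RightOFuG,OFuG,right,cortical_gm,LeftOFuG,1
154,LeftOFuG,OFuG,left,cortical_gm,RightOFuG,1
155,RightOpIFG,OpIFG,right,cortical_gm,LeftOpIFG,1
156,LeftOpIFG,OpIFG,left,cortical_gm,RightOpIFG,1
157,RightOrIFG,OrIFG,right,cortical_gm,LeftOrIFG,1
158,LeftOrIFG,OrIFG,left,cortical_gm,RightOrIFG,1
159,RightPCgG,PCgG,right,cortical_gm,LeftPCgG,1
160,LeftPCgG,PCgG,left,cortical_gm,RightPCgG,1
161,RightPCu,PCu,right,cortical_gm,LeftPCu,1
162,LeftPCu,PCu,left,cortical_gm,RightPCu,1
163,RightPHG,PHG,right,cortical_gm,LeftPHG,1
164,LeftPHG,PHG,left,cortical_gm,RightPHG,1
165,RightPIns,PIns,right,cortical_gm,LeftPIns,1
166,LeftPIns,PIns,left,cortical_gm,RightPIns,1
167,RightPO,PO,right,cortical_gm,LeftPO,1
168,LeftPO,PO,left,cortical_gm,RightPO,1
169,RightPoG,PoG,right,cortical_gm,LeftPoG,1
170,LeftPoG,PoG,left,cortical_gm,RightPoG,1
171,RightPOrG,POrG,right,cortical_gm,LeftPOrG,1
172,LeftPOrG,POrG,left,cortical_gm,RightPOrG,1
173,RightPP,PP,right,cortical_gm,LeftPP,1
174,LeftPP,PP,left,cortical_gm,RightPP,1
175,RightPrG,PrG,right,cortical_gm,LeftPrG,1
176,LeftPrG,PrG,left,cortical_gm,RightPrG,1
177,RightPT,PT,right,cortical_gm,LeftPT,1
178,LeftPT,PT,left,cortical_gm,RightPT,1
179,RightSCA,SCA,right,cortical_gm,LeftSCA,1
180,LeftSCA,SCA,left,cortical_gm,RightSCA,1
181,RightSFG,SFG,right,cortical_gm,LeftSFG,1
182,LeftSFG,SFG,left,cortical_gm,RightSFG,1
183,RightSMC,SMC,right,cortical_gm,LeftSMC,1
184,LeftSMC,SMC,left,cortical_gm,RightSMC,1
185,RightSMG,SMG,right,cortical_gm,LeftSMG,1
186,LeftSMG,SMG,left,cortical_gm,RightSMG,1
187,RightSOG,SOG,right,cortical_gm,LeftSOG,1
188,LeftSOG,SOG,left,cortical_gm,RightSOG,1
189,RightSPL,SPL,right,cortical_gm,LeftSPL,1
190,LeftSPL,SPL,left,cortical_gm,RightSPL,1
191,RightSTG,STG,right,cortical_gm,LeftSTG,1
192,LeftSTG,STG,left,cortical_gm,RightSTG,1
193,RightTMP,TMP,right,cortical_gm,LeftTMP,1
194,LeftTMP,TMP,left,cortical_gm,RightTMP,1
195,RightTrIFG,TrIFG,right,cortical_gm,LeftTrIFG,1
196,LeftTrIFG,TrIFG,left,cortical_gm,RightTrIFG,1
197,RightTTG,TTG,right,cortical_gm,LeftTTG,1
198,LeftTTG,TTG,left,cortical_gm,RightTTG,1
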