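group,label,range_start,range_end,scope,overlap
all_cause,All-cause,A00,Z99,principal,0
infectious_parasitic,Infectious and parasitic diseases,A00,B99,principal,0
bacterial_enteritis,Bacterial enteritis,A00,A09,principal,1
blood_immune,Blood and immune system disorders,D50,D89,principal,0
endocrine_metabolic,"Endocrine, nutritional, metabolic diseases",E00,E85,principal,0
endocrine_metabolic,"Endocrine, nutritional, metabolic diseases",E88,E89,principal,0
mental_behavioral,"Mental, behavioral disorders",F00,F99,principal,0
nervous_system,Nervous system diseases,G00,G99,principal,0
otitis_media_externa,Otitis media and externa,H60,H60,principal,0
otitis_media_externa,Otitis media and externa,H65,H67,principal,0
cardiovascular,Cardiovascular diseases,I00,I99,principal,0
respiratory,Respiratory system diseases,J00,J99,principal,0
asthma,Asthma,J45,J45,principal,1
digestive,Digestive system diseases,K00,K93,principal,0
skin_soft_tissue_infections,Skin and soft tissue infections,L00,L08,principal,0
other_skin_soft_tissue,Other skin and soft tissue diseases,L09,L99,principal,0
musculoskeletal,Musculoskeletal system diseases,M00,M99,principal,0
genitourinary,Genitourinary system diseases,N00,N99,principal,0
perinatal,Perinatal conditions,P00,P96,principal,0
signs_symptoms,Other signs and symptoms,R00,R99,principal,0
suicidality_depression,Suicidality and depression,R45.85,R45.87,principal,1
suicidality_depression,Suicidality and depression,R45.1,R45.1,principal,1
suicidality_depression,Suicidality and depression,R45.4,R45.6,principal,1
suicidality_depression,Suicidality and depression,F32,F32,principal,1
suicidality_depression,Suicidality and depression,F33,F33,principal,1
injury_poisoning,Injury and poisoning,S00,T66,principal,0
injury_poisoning,Injury and poisoning,T68,T88,principal,0
heat_related,Heat-related illness,T67,T67,any_mention,0
heat_related,Heat-related illness,E86,E86,any_mention,0
heat_related,Heat-related illness,E87,E87,any_mention,0
external_causes,External causes and other health factors,V01,Z99,principal,0
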