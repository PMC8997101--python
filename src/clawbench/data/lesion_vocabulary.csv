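code,name,group,alarm_min_severity,severity_sensitive,dd_associated,is_lesion
TS,Thin sole,TS,,0,0,1
IP,Interdigital phlegmon,IP,1,0,0,1
SW,Swelling of coronet and/or bulb (deep digital sepsis),SW,1,0,0,1
HF-V,Vertical horn fissure,HF,,0,0,1
HF-H,Horizontal horn fissure,HF,,0,0,1
HF-AX,Axial horn fissure,HF,,0,0,1
HF-P,Penetrating infected horn fissure,HF,1,0,0,1
IH,Interdigital hyperplasia,IH,,0,0,1
DS,Double sole,DS,,1,0,1
CC,Corkscrew claw,CC,,0,0,1
HHE,Heel horn erosion,HHE,,1,0,1
SH-D,Sole haemorrhage diffuse,SH,,1,0,1
SH-C,Sole haemorrhage circumscribed,SH,,1,0,1
WLD,White line disease,WLA,2,1,0,1
SU,Sole ulcer,UL,1,0,0,1
TU,Toe ulcer,UL,1,0,0,1
BU,Bulb ulcer,UL,1,0,0,1
TN,Toe necrosis,UL,1,0,0,1
CD,Concave dorsal wall (laminitis),CD,,0,0,1
ID,Interdigital dermatitis,other,,0,0,1
SC,Scissor claw,other,,0,0,1
OG,Claw overgrowth,other,,0,0,1
M0,Digital dermatitis stage M0 (healthy skin),,,0,0,0
M1,Digital dermatitis stage M1 (early),DD,,0,0,1
M2,Digital dermatitis stage M2 (acute ulcerative),DD,1,0,0,1
M3,Digital dermatitis stage M3 (healing),DD,,0,0,1
M4,Digital dermatitis stage M4 (chronic),DD,,0,0,1
M4.1,Digital dermatitis stage M4.1 (chronic with reactivation),DD,,0,0,1
WLD-DD,Non-healing white line disease (DD-associated),WLA,1,0,1,1
SU-DD,Non-healing sole ulcer (DD-associated),UL,1,0,1,1
BU-DD,Non-healing bulb ulcer (DD-associated),UL,1,0,1,1
TN-DD,DD-associated toe necrosis,UL,1,0,1,1
NL,No lesion recorded,,,0,0,0
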