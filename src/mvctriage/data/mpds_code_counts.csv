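code,descriptor,not_ls,ls
29D1,Major incident,7,1
29D1V,"Major incident, multiple patients",2,0
29D1b,Major incident - bus,5,1
29D1d,Major incident - train,1,2
29D1f,Major incident - multiple vehicle (>= 10) pile-up,4,0
29D2,High mechanism,257,78
29D2k,High mechanism - all-terrain/snowmobile,2,0
29D2l,High mechanism - vehicle v. bicycle/motorcycle,905,247
29D2m,High mechanism - vehicle v. pedestrian,672,169
29D2n,High mechanism - ejection,80,34
29D2p,High mechanism - rollovers,377,67
29D2r,High mechanism - possible death at scene,0,1
29D3,HAZMAT,67,10
29D3U,"HAZMAT, unknown number of patients",3,1
29D3V,"HAZMAT, multiple patients",19,3
29D3X,"HAZMAT, unknown number of patients and additional response required",1,0
29D3Y,"HAZMAT, multiple patients and additional response required",3,0
29D4,Trapped victim,338,126
29D4U,"Trapped victim, unknown number of patients",59,23
29D4V,"Trapped victim, multiple patients",124,64
29D4X,"Trapped victim, unknown number of patients and additional response required",3,2
29D4Y,"Trapped victim, multiple patients and additional response required",28,21
29D4n,"Trapped victim, ejection",3,0
29D5,Not alert,325,153
29D5U,"Not alert, unknown number of patients",5,2
29D5V,"Not alert, multiple patients",47,21
29D5X,"Not alert, unknown number of patients and additional response required",0,1
29D5Y,"Not alert, multiple patients and additional response required",3,2
29D5m,"Not alert, vehicle v. pedestrian",0,2
29D5n,"Not alert, ejection",2,4
29B1,Injuries,2098,237
29B1U,"Injuries, unknown number of patients",41,8
29B1V,"Injuries, multiple patients",470,56
29B1X,"Injuries, unknown number of patients and additional response required",6,1
29B1Y,"Injuries, multiple patients and additional response required",57,5
29B2,Serious haemorrhage,126,31
29B2V,"Serious haemorrhage, multiple patients",23,3
29B2X,"Serious haemorrhage, unknown number of patients and additional response required",1,0
29B2Y,"Serious haemorrhage, multiple patients and additional response required",5,3
29B3,Other hazards,589,76
29B3U,"Other hazards, unknown number of patients",71,8
29B3V,"Other hazards, multiple patients",214,29
29B3X,"Other hazards, unknown number of patients and additional response required",6,2
29B3Y,"Other hazards, multiple patients and additional response required",33,4
29B4,Unknown status/Other codes not applicable,2054,185
29B4U,"Unknown status/Other codes not applicable, unknown number of patients",429,36
29B4V,"Unknown status/Other codes not applicable, multiple patients",442,37
29B4X,"Unknown status/Other codes not applicable, unknown number of patients and additional response required",29,4
29B4Y,"Unknown status/Other codes not applicable, multiple patients and additional response required",31,5
29A1,1st party caller with injury to not dangerous body area,16,0
29A1V,"1st party caller with injury to not dangerous body area, multiple patients",1,0
29O1,No injuries (confirmed),116,6
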