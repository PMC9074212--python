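variable,category,not_ls,ls
accident_type,Intersection,4230,653
accident_type,Midblock,2513,586
airbag_deployed,Any airbag deployed,3280,571
airbag_deployed,No airbag deployed,6920,1200
road_alignment,Curve,861,206
road_alignment,Straight,4669,850
atmosphere,Clear,3207,694
atmosphere,Dust/Smoke,5,1
atmosphere,Fog/Mist,12,3
atmosphere,Fog/smoke/dust,0,1
atmosphere,Overcast,277,90
atmosphere,Raining,358,55
day_of_week,Monday,1384,189
day_of_week,Tuesday,1481,261
day_of_week,Wednesday,1537,234
day_of_week,Thursday,1552,271
day_of_week,Friday,1683,297
day_of_week,Saturday,1360,258
day_of_week,Sunday,1203,261
anyone_ejected,Anyone ejected,63,62
anyone_ejected,No one ejected,10137,1709
road_grade,Crest of hill,78,18
road_grade,Level,3321,668
road_grade,Slope,666,186
lighting,Daylight,4867,824
lighting,Dawn/Dusk,479,75
lighting,Dark - street lights on,1095,257
lighting,Dark - street lights off,19,6
lighting,Dark - street lights not provided,69,46
anyone_not_ambulant,Anyone not ambulant,140,116
anyone_not_ambulant,Everyone ambulant,10060,1655
older,Any aged >= 75 years,739,120
older,Everyone aged <= 74 years,9461,1651
single_v_multi_vehicle,2 or more vehicles,5314,689
single_v_multi_vehicle,Single vehicle,1423,326
road_surface,Sealed,3321,668
road_surface,Unsealed,78,18
rollover,Any vehicle rolled,377,67
rollover,No vehicle rolled,9823,1704
anyone_trapped,Anyone trapped,444,303
anyone_trapped,No one trapped,9756,1468
child,Anyone aged <= 12 years,455,92
child,Everyone aged >= 13 years,9745,1679
vulnerable_road_user,Motor vehicle occupant,6866,854
vulnerable_road_user,Vulnerable,1943,536
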