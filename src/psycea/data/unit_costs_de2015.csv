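item,unit_label,unit_cost_eur,category,source
psychiatric_inpatient_day,day,386,inpatient,local clinic
somatic_inpatient_day,day,576,inpatient,remuneration index
day_care_day,day,168,day_care,local clinic
psychiatrist_visit,visit,45,outpatient,remuneration index
gp_visit,visit,20,outpatient,remuneration index
sheltered_workplace_day,day,48,complementary,administrative district
occupational_therapy_unit,unit,38,complementary,remuneration index
physical_therapy_unit,unit,16,complementary,remuneration index
day_structuring_unit,unit,33,complementary,remuneration index
contact_counseling_center_visit,visit,29,complementary,local service provider
home_nursing_visit,visit,22,complementary,cost agreement providers/insurer
police_contact,contact,62,other,state ordinance on administrative fees
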