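item,unit,price,source
staff_surgeon_per_min,minute,2.00,staff bands
staff_anaesthetist_per_min,minute,2.00,staff bands
staff_nurse_band5_per_min,minute,0.62,staff bands
staff_nurse_band4_per_min,minute,0.55,staff bands
theatre_per_min,minute,20.00,theatre
recovery_per_min,minute,1.50,theatre
device_intervention,item,400.00,list price
device_comparator,item,400.00,list price
anaesthesia_general,episode,60.00,medications
anaesthesia_spinal,episode,45.00,medications
anaesthesia_la_iv,episode,30.00,medications
anaesthesia_la_oral,episode,15.00,medications
anaesthesia_la,episode,10.00,medications
inpatient_day,day,350.00,reference costs
catheter,item,8.00,catheters
return_to_theatre,episode,900.00,reference costs
gp_visit,visit,39.00,primary care
physio_visit,visit,54.00,primary care
district_nurse_visit,visit,43.00,primary care
outpatient_visit,visit,125.00,reference costs
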