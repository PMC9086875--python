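item_id,unit_cost_eur,price_year,source
the_box,318,2020,Department bills (ECG monitor; blood pressure monitor; weight scale; box; manual)
stress_echo,542,2020,LUMC
tte,117,2020,LUMC
holter,152,2020,LUMC
e_visit,44,2020,LUMC micro-costing: subscription / 5500 capacity x 1.22 overhead
in_office,96,2020,LUMC micro-costing: component costs x 1.44 overhead
technical_support,1758,2020,Vendor bills
np_contact,4,2020,Dutch costing manual (nurse practitioner contact)
catheterization,2037,2020,NZA tariff (coronary angiogram)
single_vessel_pci,5999,2020,NZA tariff (elective 1-vessel revascularization with admission)
multivessel_pci,6428,2020,NZA tariff (elective multivessel revascularization with admission)
hospitalization,684,2020,Dutch costing manual (admission price per night)
inhospital_support,15367,2020,UMC gross salary 0.5 FTE (training and data checking)
emergency,286,2020,Dutch costing manual (emergency care visit)
box_support,194.60227272727272,2020,Allocated shared support: (15367 + 1758) / 88 patients
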