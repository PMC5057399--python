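item_id,model,discrimination,step_1,step_2,step_3
FAI 13: household/car maintenance,rasch_dichotomous,1.0,4.73,,
FAI 14: reading books,rasch_dichotomous,1.0,4.72,,
FAI 15: gainful work,rasch_dichotomous,1.0,4.01,,
FAI 12: gardening,rasch_dichotomous,1.0,3.75,,
FAI 9: actively pursuing hobbies,rasch_dichotomous,1.0,3.53,,
FAI 11: travel outings/car rides,rasch_dichotomous,1.0,3.52,,
FAI 1: preparing main meals,rasch_dichotomous,1.0,3.24,,
FAI 3: washing clothes,rasch_dichotomous,1.0,3.19,,
FAI 2: washing up,rasch_dichotomous,1.0,3.09,,
FAI 5: heavy housework,rasch_dichotomous,1.0,2.75,,
FAI 4: light housework,rasch_dichotomous,1.0,1.95,,
FAI 10: driving a car/bus travel,rasch_dichotomous,1.0,1.83,,
FAI 6: local shopping,rasch_dichotomous,1.0,0.59,,
BI 2: bathing,rasch_dichotomous,1.0,0.55,,
BI 10: climbing stairs,rasch_dichotomous,1.0,-0.72,,
BI 4: dressing,rasch_dichotomous,1.0,-0.77,,
BI 9: mobility,rasch_dichotomous,1.0,-2.85,,
BI 7: toileting,rasch_dichotomous,1.0,-3.48,,
BI 8: transfer,rasch_dichotomous,1.0,-3.99,,
BI 3: grooming,rasch_dichotomous,1.0,-6.77,,
BI 6: bladder control,rasch_dichotomous,1.0,-7.09,,
BI 5: bowel control,rasch_dichotomous,1.0,-7.33,,
BI 1: eating,rasch_dichotomous,1.0,-8.41,,
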