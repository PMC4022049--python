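state,vials_per_year,lcl,ucl
signs_symptoms,76,62,91
recovery,63,49,75
splenectomy,78,50,111
bone_complication,102,75,132
multiple_complications,86,70,102
malignancy,130,68,209
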