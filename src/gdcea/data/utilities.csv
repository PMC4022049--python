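state,tariff,mean,lcl,ucl
asymptomatic,UK,0.93,0.89,0.97
signs_symptoms,UK,0.8716,0.8177,0.9225
recovery,UK,0.8716,0.8177,0.9225
splenectomy,UK,0.7532,0.6768,0.8215
bone_complication,UK,0.8614,0.753,0.9685
multiple_complications,UK,0.7323,0.6601,0.8202
malignancy,UK,0.15,,
asymptomatic,NL,0.93,0.89,0.97
signs_symptoms,NL,0.8897,0.841,0.9349
recovery,NL,0.8897,0.841,0.9349
splenectomy,NL,0.7781,0.699,0.8626
bone_complication,NL,0.8882,0.8027,0.9707
multiple_complications,NL,0.7981,0.743,0.8638
malignancy,NL,0.364,,
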