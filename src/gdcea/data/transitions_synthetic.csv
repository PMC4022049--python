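strategy,from,to,mean_p,lcl,ucl,alpha,beta,source_label
no_ert,asymptomatic,signs_symptoms,0.05,0.010611,0.117148,3.0,57.0,synthetic placeholder
no_ert,signs_symptoms,splenectomy,0.045,0.008455,0.109516,2.6999999999999997,57.3,synthetic placeholder
no_ert,signs_symptoms,bone_complication,0.008,6e-06,0.040609,0.48,59.519999999999996,synthetic placeholder
no_ert,signs_symptoms,malignancy,0.002,0.0,0.018416,0.12,59.88,synthetic placeholder
no_ert,splenectomy,multiple_complications,0.06,0.015352,0.131928,3.5999999999999996,56.4,synthetic placeholder
no_ert,splenectomy,malignancy,0.004,0.0,0.027855,0.24,59.76,synthetic placeholder
no_ert,bone_complication,multiple_complications,0.06,0.015352,0.131928,3.5999999999999996,56.4,synthetic placeholder
no_ert,bone_complication,malignancy,0.004,0.0,0.027855,0.24,59.76,synthetic placeholder
no_ert,multiple_complications,malignancy,0.008,6e-06,0.040609,0.48,59.519999999999996,synthetic placeholder
ert_base,asymptomatic,signs_symptoms,0.05,0.010611,0.117148,3.0,57.0,synthetic placeholder
ert_base,signs_symptoms,recovery,0.1,0.038244,0.186794,6.0,54.0,synthetic placeholder
ert_base,signs_symptoms,splenectomy,0.004,0.0,0.027855,0.24,59.76,synthetic placeholder
ert_base,signs_symptoms,bone_complication,0.006,0.0,0.034788,0.36,59.64,synthetic placeholder
ert_base,signs_symptoms,malignancy,0.001,0.0,0.011114,0.06,59.94,synthetic placeholder
ert_base,recovery,splenectomy,0.003,0.0,0.023627,0.18,59.82,synthetic placeholder
ert_base,recovery,bone_complication,0.005,0.0,0.03151,0.3,59.7,synthetic placeholder
ert_base,recovery,malignancy,0.001,0.0,0.011114,0.06,59.94,synthetic placeholder
ert_base,splenectomy,multiple_complications,0.025,0.001835,0.076481,1.5,58.5,synthetic placeholder
ert_base,splenectomy,malignancy,0.003,0.0,0.023627,0.18,59.82,synthetic placeholder
ert_base,bone_complication,multiple_complications,0.03,0.003121,0.085238,1.7999999999999998,58.199999999999996,synthetic placeholder
ert_base,bone_complication,malignancy,0.003,0.0,0.023627,0.18,59.82,synthetic placeholder
ert_base,multiple_complications,malignancy,0.006,0.0,0.034788,0.36,59.64,synthetic placeholder
ert_historical,asymptomatic,signs_symptoms,0.05,0.010611,0.117148,3.0,57.0,synthetic placeholder
ert_historical,signs_symptoms,recovery,0.08,0.026154,0.160045,4.8,55.2,synthetic placeholder
ert_historical,signs_symptoms,splenectomy,0.005,0.0,0.03151,0.3,59.7,synthetic placeholder
ert_historical,signs_symptoms,bone_complication,0.008,6e-06,0.040609,0.48,59.519999999999996,synthetic placeholder
ert_historical,signs_symptoms,malignancy,0.002,0.0,0.018416,0.12,59.88,synthetic placeholder
ert_historical,recovery,splenectomy,0.004,0.0,0.027855,0.24,59.76,synthetic placeholder
ert_historical,recovery,bone_complication,0.006,0.0,0.034788,0.36,59.64,synthetic placeholder
ert_historical,recovery,malignancy,0.001,0.0,0.011114,0.06,59.94,synthetic placeholder
ert_historical,splenectomy,multiple_complications,0.03,0.003121,0.085238,1.7999999999999998,58.199999999999996,synthetic placeholder
ert_historical,splenectomy,malignancy,0.004,0.0,0.027855,0.24,59.76,synthetic placeholder
ert_historical,bone_complication,multiple_complications,0.035,0.004679,0.09361,2.1,57.9,synthetic placeholder
ert_historical,bone_complication,malignancy,0.004,0.0,0.027855,0.24,59.76,synthetic placeholder
ert_historical,multiple_complications,malignancy,0.008,6e-06,0.040609,0.48,59.519999999999996,synthetic placeholder
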