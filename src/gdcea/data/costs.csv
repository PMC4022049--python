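state,component,mean,lcl,ucl
asymptomatic,ert,0,,
signs_symptoms,ert,151147,123501.0,180088.0
recovery,ert,124183,97529.0,149041.0
splenectomy,ert,155082,98443.0,220004.0
bone_complication,ert,202348,149319.0,261573.0
multiple_complications,ert,170317,138201.0,202653.0
malignancy,ert,257469,135582.0,414084.0
asymptomatic,hospital,1470,455.0,2152.0
signs_symptoms,hospital,2887,1974.0,3885.0
recovery,hospital,3055,1708.0,4858.0
splenectomy,hospital,4836,2544.0,7145.0
bone_complication,hospital,4337,1590.0,9313.0
multiple_complications,hospital,2194,1652.0,2826.0
malignancy,hospital,27523,4786.0,51722.0
asymptomatic,out_of_hospital,0,,
signs_symptoms,out_of_hospital,121,31.0,272.0
recovery,out_of_hospital,641,229.0,1097.0
splenectomy,out_of_hospital,299,8.0,589.0
bone_complication,out_of_hospital,449,51.0,939.0
multiple_complications,out_of_hospital,245,97.0,421.0
malignancy,out_of_hospital,56,,
asymptomatic,production_loss,0,,
signs_symptoms,production_loss,0,0.0,0.0
recovery,production_loss,0,0.0,0.0
splenectomy,production_loss,13698,0.0,27396.0
bone_complication,production_loss,10002,0.0,20004.0
multiple_complications,production_loss,10615,0.0,21230.0
malignancy,production_loss,73057,,
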