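study_id,metric,predicted,observed
study_01,cmax,8.1,7.8
study_01,auc,298.3,341.4
study_01,tmax,4.4,5.0
study_02,cmax,7.2,7.6
study_02,auc,264.1,272.0
study_02,tmax,4.9,3.0
study_03,cmax,7.0,5.4
study_03,auc,217.8,236.7
study_03,tmax,4.0,7.0
study_04,cmax,13.4,13.2
study_04,auc,426.2,436.9
study_04,tmax,4.3,6.0
study_05,cmax,17.2,17.5
study_05,auc,710.3,711.5
study_05,tmax,3.9,7.0
study_06,cmax,14.5,16.7
study_06,auc,651.7,629.2
study_06,tmax,4.2,5.0
study_07,cmax,14.0,11.2
study_07,auc,436.5,460.3
study_07,tmax,4.0,4.8
study_08,cmax,21.0,19.0
study_08,auc,653.1,755.1
study_08,tmax,4.0,6.2
study_09,cmax,24.8,19.7
study_09,auc,423.1,388.6
study_09,tmax,3.7,6.2
study_10,cmax,92.2,115.6
study_10,auc,1731.0,2220.0
study_10,tmax,3.0,4.0
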