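wave,covariate,category,share_pct,prevalence_pct
2006,education,primary-or-less,64.7,5.2
2006,education,secondary,31.9,14.3
2006,education,higher,3.4,25.4
2012,education,primary-or-less,53.2,17.1
2012,education,secondary,40.8,30.1
2012,education,higher,6.1,45.2
2016-17,education,primary-or-less,46.0,15.4
2016-17,education,secondary,46.4,24.9
2016-17,education,higher,7.6,34.9
2006,age_group,<25,31.8,10.0
2006,age_group,25-34,33.4,12.0
2006,age_group,35+,34.9,4.7
2012,age_group,<25,32.3,25.9
2012,age_group,25-34,34.9,30.5
2012,age_group,35+,32.7,15.6
2016-17,age_group,<25,31.3,20.7
2016-17,age_group,25-34,34.5,26.6
2016-17,age_group,35+,34.1,16.6
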