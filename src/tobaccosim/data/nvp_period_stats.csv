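survey,gender,age_group,reduction_pct,reduction_lo_pct,reduction_hi_pct,net_impact_pct,net_lo_pct,net_hi_pct,annual_pct,annual_lo_pct,annual_hi_pct,annual_diff_pct,annual_diff_lo_pct,annual_diff_hi_pct
model,male,18+,12.2,,,,,,2.1,,,,,
tus_cps,male,18+,21.9,19.7,23.9,9.7,7.5,11.7,4.0,3.6,4.5,1.9,1.4,2.3
nhis,male,18+,22.9,19.0,26.8,10.7,6.8,14.6,4.2,3.5,5.1,2.1,1.3,2.9
model,male,18-24,5.2,,,,,,0.9,,,,,
tus_cps,male,18-24,48.4,41.6,54.5,43.2,36.4,49.3,10.4,8.6,12.3,9.6,7.7,11.4
nhis,male,18-24,57.8,47.8,68.2,52.6,42.6,63.0,13.4,10.3,17.4,12.5,9.4,16.5
model,male,25-44,7.5,,,,,,1.3,,,,,
tus_cps,male,25-44,24.3,21.0,27.3,16.8,13.5,19.8,4.5,3.9,5.2,3.3,2.6,3.9
nhis,male,25-44,24.8,18.5,31.1,17.3,11.0,23.6,4.6,3.4,6.0,3.3,2.1,4.7
model,male,45-64,17.4,,,,,,3.1,,,,,
tus_cps,male,45-64,14.9,11.6,18.2,-2.5,-5.8,0.8,2.6,2.0,3.3,-0.5,-1.1,0.2
nhis,male,45-64,9.3,2.5,16.3,-8.1,-14.9,-1.1,1.6,0.4,2.9,-1.5,-2.7,-0.2
model,male,65+,11.4,,,,,,2.0,,,,,
tus_cps,male,65+,3.2,-3.0,8.5,-8.2,-14.4,-2.8,0.5,-0.5,1.5,-1.4,-2.5,-0.5
nhis,male,65+,6.2,-4.7,17.9,-5.2,-16.1,6.6,1.1,-0.8,3.2,-0.9,-2.8,1.2
model,female,18+,12.8,,,,,,2.3,,,,,
tus_cps,female,18+,23.6,22.0,25.8,10.7,9.1,13.0,4.4,4.1,4.9,2.1,1.8,2.6
nhis,female,18+,24.2,20.3,28.5,11.3,7.4,15.6,4.5,3.7,5.4,2.2,1.4,3.2
model,female,18-24,5.3,,,,,,0.9,,,,,
tus_cps,female,18-24,51.2,44.1,57.7,45.9,38.9,52.4,11.3,9.3,13.4,10.4,8.3,12.5
nhis,female,18-24,49.7,35.2,64.1,44.4,29.9,58.8,10.8,7.0,15.7,9.9,6.1,14.8
model,female,25-44,9.2,,,,,,1.6,,,,,
tus_cps,female,25-44,28.9,25.6,31.6,19.8,16.4,22.4,5.5,4.8,6.1,3.9,3.2,4.5
nhis,female,25-44,20.2,12.9,27.5,11.1,3.8,18.4,3.7,2.3,5.2,2.1,0.7,3.6
model,female,45-64,17.6,,,,,,3.2,,,,,
tus_cps,female,45-64,14.5,11.1,17.6,-3.1,-6.5,0.0,2.6,1.9,3.2,-0.6,-1.2,0.0
nhis,female,45-64,24.5,18.0,30.7,6.9,0.4,13.1,4.6,3.3,5.9,1.4,0.1,2.8
model,female,65+,7.7,,,,,,1.3,,,,,
tus_cps,female,65+,6.9,1.5,11.8,-0.8,-6.2,4.1,1.2,0.2,2.1,-0.1,-1.1,0.7
nhis,female,65+,2.5,-9.3,14.7,-5.2,-17.0,7.0,0.4,-1.5,2.6,-0.9,-2.8,1.3
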