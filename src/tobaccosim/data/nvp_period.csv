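survey,gender,age_group,year,prevalence_pct,ci_lower_pct,ci_upper_pct
model,male,18+,2012,17.3,,
model,male,18+,2018,15.2,,
tus_cps,male,18+,2012,16.6,,
tus_cps,male,18+,2018,12.9,12.6,13.3
nhis,male,18+,2012,20.5,,
nhis,male,18+,2018,15.8,15.0,16.6
model,male,18-24,2012,19.9,,
model,male,18-24,2018,18.8,,
tus_cps,male,18-24,2012,16.9,,
tus_cps,male,18-24,2018,8.7,7.7,9.9
nhis,male,18-24,2012,20.1,,
nhis,male,18-24,2018,8.5,6.4,10.5
model,male,25-44,2012,19.6,,
model,male,25-44,2018,18.2,,
tus_cps,male,25-44,2012,19.1,,
tus_cps,male,25-44,2018,14.5,13.9,15.1
nhis,male,25-44,2012,25.4,,
nhis,male,25-44,2018,19.1,17.5,20.7
model,male,45-64,2012,18.2,,
model,male,45-64,2018,15.0,,
tus_cps,male,45-64,2012,18.2,,
tus_cps,male,45-64,2018,15.5,14.9,16.1
nhis,male,45-64,2012,20.2,,
nhis,male,45-64,2018,18.3,16.9,19.7
model,male,65+,2012,8.4,,
model,male,65+,2018,7.4,,
tus_cps,male,65+,2012,8.6,,
tus_cps,male,65+,2018,8.4,7.9,8.9
nhis,male,65+,2012,10.6,,
nhis,male,65+,2018,9.9,8.7,11.1
model,female,18+,2012,13.5,,
model,female,18+,2018,11.8,,
tus_cps,female,18+,2012,13.1,,
tus_cps,female,18+,2018,10.0,9.7,10.2
nhis,female,18+,2012,15.8,,
nhis,female,18+,2018,12.0,11.3,12.6
model,female,18-24,2012,15.7,,
model,female,18-24,2018,14.9,,
tus_cps,female,18-24,2012,12.5,,
tus_cps,female,18-24,2018,6.1,5.3,7.0
nhis,female,18-24,2012,14.5,,
nhis,female,18-24,2018,7.3,5.2,9.4
model,female,25-44,2012,15.7,,
model,female,25-44,2018,14.2,,
tus_cps,female,25-44,2012,14.9,,
tus_cps,female,25-44,2018,10.6,10.2,11.1
nhis,female,25-44,2012,17.8,,
nhis,female,25-44,2018,14.2,12.9,15.5
model,female,45-64,2012,14.4,,
model,female,45-64,2018,11.9,,
tus_cps,female,45-64,2012,15.4,,
tus_cps,female,45-64,2018,13.2,12.7,13.7
nhis,female,45-64,2012,18.9,,
nhis,female,45-64,2018,14.3,13.1,15.5
model,female,65+,2012,7.1,,
model,female,65+,2018,6.6,,
tus_cps,female,65+,2012,6.8,,
tus_cps,female,65+,2018,6.3,6.0,6.7
nhis,female,65+,2012,7.5,,
nhis,female,65+,2018,7.3,6.4,8.2
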