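survey,gender,age_group,year,prevalence_pct,ci_lower_pct,ci_upper_pct
model,male,18+,1993,26.7,,
model,male,18+,1998,25.2,,
model,male,18+,2010,17.9,,
model,male,18+,2012,17.3,,
tus_cps,male,18+,1993,26.6,26.3,27.0
tus_cps,male,18+,1998,24.4,23.9,25.0
tus_cps,male,18+,2010,17.2,16.8,17.6
nhis,male,18+,1993,27.7,26.6,28.8
nhis,male,18+,1998,26.4,25.5,27.3
nhis,male,18+,2010,21.5,20.7,22.3
nhis,male,18+,2012,20.5,19.6,21.4
model,male,18-24,1993,27.3,,
model,male,18-24,1998,29.0,,
model,male,18-24,2010,19.8,,
model,male,18-24,2012,19.9,,
tus_cps,male,18-24,1993,27.7,26.7,28.7
tus_cps,male,18-24,1998,30.0,27.9,32.0
tus_cps,male,18-24,2010,19.4,18.0,20.7
nhis,male,18-24,1993,28.8,25.5,32.1
nhis,male,18-24,1998,31.3,28.4,34.2
nhis,male,18-24,2010,22.8,19.9,25.7
nhis,male,18-24,2012,20.1,17.1,23.1
model,male,25-44,1993,30.7,,
model,male,25-44,1998,28.1,,
model,male,25-44,2010,20.2,,
model,male,25-44,2012,19.6,,
tus_cps,male,25-44,1993,30.8,30.3,31.3
tus_cps,male,25-44,1998,28.4,27.5,29.4
tus_cps,male,25-44,2010,19.6,19.0,20.3
nhis,male,25-44,1993,31.1,29.5,32.7
nhis,male,25-44,1998,29.4,28.1,30.7
nhis,male,25-44,2010,24.3,22.8,25.8
nhis,male,25-44,2012,25.4,23.8,27.1
model,male,45-64,1993,27.0,,
model,male,45-64,1998,26.0,,
model,male,45-64,2010,19.1,,
model,male,45-64,2012,18.2,,
tus_cps,male,45-64,1993,27.1,26.5,27.7
tus_cps,male,45-64,1998,25.1,24.1,26.2
tus_cps,male,45-64,2010,18.7,18.1,19.3
nhis,male,45-64,1993,29.2,27.2,31.2
nhis,male,45-64,1998,27.7,26.1,29.3
nhis,male,45-64,2010,23.2,21.6,24.8
nhis,male,45-64,2012,20.2,18.8,21.6
model,male,65+,1993,13.6,,
model,male,65+,1998,11.6,,
model,male,65+,2010,8.5,,
model,male,65+,2012,8.4,,
tus_cps,male,65+,1993,13.4,12.8,14.0
tus_cps,male,65+,1998,10.7,9.7,11.7
tus_cps,male,65+,2010,8.6,7.9,9.2
nhis,male,65+,1993,13.5,11.3,15.7
nhis,male,65+,1998,10.4,9.1,11.7
nhis,male,65+,2010,9.7,8.3,11.1
nhis,male,65+,2012,10.6,9.3,12.0
model,female,18+,1993,22.2,,
model,female,18+,1998,20.3,,
model,female,18+,2010,14.0,,
model,female,18+,2012,13.5,,
tus_cps,female,18+,1993,22.3,22.1,22.6
tus_cps,female,18+,1998,20.0,19.5,20.4
tus_cps,female,18+,2010,13.7,13.4,14.0
nhis,female,18+,1993,22.5,21.6,23.4
nhis,female,18+,1998,22.0,21.2,22.8
nhis,female,18+,2010,17.3,16.5,18.1
nhis,female,18+,2012,15.8,15.1,16.5
model,female,18-24,1993,23.7,,
model,female,18-24,1998,23.9,,
model,female,18-24,2010,15.7,,
model,female,18-24,2012,15.7,,
tus_cps,female,18-24,1993,23.9,23.0,24.7
tus_cps,female,18-24,1998,24.7,23.0,26.5
tus_cps,female,18-24,2010,14.7,13.7,15.8
nhis,female,18-24,1993,22.9,20.2,25.6
nhis,female,18-24,1998,24.5,21.9,27.1
nhis,female,18-24,2010,17.4,15.0,19.8
nhis,female,18-24,2012,14.5,12.3,16.7
model,female,25-44,1993,26.3,,
model,female,25-44,1998,23.4,,
model,female,25-44,2010,16.2,,
model,female,25-44,2012,15.7,,
tus_cps,female,25-44,1993,26.4,26.0,26.8
tus_cps,female,25-44,1998,23.8,23.0,24.6
tus_cps,female,25-44,2010,15.7,15.1,16.2
nhis,female,25-44,1993,27.3,26.0,28.6
nhis,female,25-44,1998,25.6,24.4,26.8
nhis,female,25-44,2010,19.8,18.4,21.2
nhis,female,25-44,2012,17.8,16.6,19.0
model,female,45-64,1993,23.1,,
model,female,45-64,1998,21.5,,
model,female,45-64,2010,15.3,,
model,female,45-64,2012,14.4,,
tus_cps,female,45-64,1993,23.2,22.7,23.7
tus_cps,female,45-64,1998,20.5,19.6,21.3
tus_cps,female,45-64,2010,15.9,15.4,16.4
nhis,female,45-64,1993,23.0,21.3,24.7
nhis,female,45-64,1998,22.5,21.2,23.8
nhis,female,45-64,2010,19.1,17.9,20.3
nhis,female,45-64,2012,18.9,17.6,20.2
model,female,65+,1993,11.3,,
model,female,65+,1998,9.8,,
model,female,65+,2010,7.1,,
model,female,65+,2012,7.1,,
tus_cps,female,65+,1993,11.4,11.0,11.9
tus_cps,female,65+,1998,9.6,8.8,10.3
tus_cps,female,65+,2010,6.8,6.4,7.3
nhis,female,65+,1993,10.5,9.2,11.8
nhis,female,65+,1998,11.2,10.0,12.4
nhis,female,65+,2010,9.3,8.1,10.5
nhis,female,65+,2012,7.5,6.6,8.5
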