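survey,gender,age_group,period,change_pct
model,male,18+,1993-1998,-5.8
model,male,18+,1998-2010,-28.8
model,male,18+,1998-2012,-31.2
tus_cps,male,18+,1993-1998,-8.2
tus_cps,male,18+,1998-2010,-29.6
nhis,male,18+,1993-1998,-4.7
nhis,male,18+,1998-2010,-18.6
nhis,male,18+,1998-2012,-22.3
model,male,18-24,1993-1998,6.4
model,male,18-24,1998-2010,-31.6
model,male,18-24,1998-2012,-31.5
tus_cps,male,18-24,1993-1998,8.0
tus_cps,male,18-24,1998-2010,-35.4
nhis,male,18-24,1993-1998,8.7
nhis,male,18-24,1998-2010,-27.2
nhis,male,18-24,1998-2012,-35.8
model,male,25-44,1993-1998,-8.3
model,male,25-44,1998-2010,-28.1
model,male,25-44,1998-2012,-30.2
tus_cps,male,25-44,1993-1998,-7.7
tus_cps,male,25-44,1998-2010,-30.9
nhis,male,25-44,1993-1998,-5.5
nhis,male,25-44,1998-2010,-17.3
nhis,male,25-44,1998-2012,-13.6
model,male,45-64,1993-1998,-3.9
model,male,45-64,1998-2010,-26.3
model,male,45-64,1998-2012,-29.9
tus_cps,male,45-64,1993-1998,-7.3
tus_cps,male,45-64,1998-2010,-25.6
nhis,male,45-64,1993-1998,-5.1
nhis,male,45-64,1998-2010,-16.2
nhis,male,45-64,1998-2012,-27.1
model,male,65+,1993-1998,-14.7
model,male,65+,1998-2010,-26.8
model,male,65+,1998-2012,-27.6
tus_cps,male,65+,1993-1998,-20.2
tus_cps,male,65+,1998-2010,-20.1
nhis,male,65+,1993-1998,-23.0
nhis,male,65+,1998-2010,-6.7
nhis,male,65+,1998-2012,1.9
model,female,18+,1993-1998,-8.6
model,female,18+,1998-2010,-30.8
model,female,18+,1998-2012,-33.3
tus_cps,female,18+,1993-1998,-10.5
tus_cps,female,18+,1998-2010,-31.3
nhis,female,18+,1993-1998,-2.2
nhis,female,18+,1998-2010,-21.4
nhis,female,18+,1998-2012,-28.2
model,female,18-24,1993-1998,1.1
model,female,18-24,1998-2010,-34.4
model,female,18-24,1998-2012,-34.4
tus_cps,female,18-24,1993-1998,3.4
tus_cps,female,18-24,1998-2010,-40.3
nhis,female,18-24,1993-1998,7.0
nhis,female,18-24,1998-2010,-29.0
nhis,female,18-24,1998-2012,-40.8
model,female,25-44,1993-1998,-10.9
model,female,25-44,1998-2010,-31.0
model,female,25-44,1998-2012,-33.1
tus_cps,female,25-44,1993-1998,-9.9
tus_cps,female,25-44,1998-2010,-34.2
nhis,female,25-44,1993-1998,-6.2
nhis,female,25-44,1998-2010,-22.7
nhis,female,25-44,1998-2012,-30.5
model,female,45-64,1993-1998,-6.7
model,female,45-64,1998-2010,-28.8
model,female,45-64,1998-2012,-33.1
tus_cps,female,45-64,1993-1998,-11.9
tus_cps,female,45-64,1998-2010,-22.2
nhis,female,45-64,1993-1998,-2.2
nhis,female,45-64,1998-2010,-15.1
nhis,female,45-64,1998-2012,-16.0
model,female,65+,1993-1998,-13.5
model,female,65+,1998-2010,-27.0
model,female,65+,1998-2012,-26.9
tus_cps,female,65+,1993-1998,-16.3
tus_cps,female,65+,1998-2010,-28.6
nhis,female,65+,1993-1998,6.7
nhis,female,65+,1998-2010,-17.0
nhis,female,65+,1998-2012,-33.0
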