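country,metric,year,value
US,prevalence,2000,23.1
US,prevalence,2015,15.2
UK,prevalence,2000,27.0
UK,prevalence,2015,17.8
Canada,prevalence,2000,24.4
Canada,prevalence,2015,13.0
US,amount_per_day,2000,18.1
US,amount_per_day,2015,14.2
UK,amount_per_day,2000,13.8
UK,amount_per_day,2015,11.3
Canada,amount_per_day,2000,16.8
Canada,amount_per_day,2015,13.8
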