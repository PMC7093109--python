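country,start_year,end_year,total_sticks
US,1940,2000,32.6e12
UK,1940,2000,7.0e12
Canada,1940,2000,3.2e12
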