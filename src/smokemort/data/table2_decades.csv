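country,sex,metric,year,value,unit
US,male,attributable,1955,139,thousand
US,male,attributable,1965,235,thousand
US,male,attributable,1975,305,thousand
US,male,attributable,1985,335,thousand
US,male,attributable,1995,341,thousand
US,male,attributable,2005,302,thousand
US,male,attributable,2015,286,thousand
US,male,total,1955,882,thousand
US,male,total,1965,1036,thousand
US,male,total,1975,1063,thousand
US,male,total,1985,1092,thousand
US,male,total,1995,1163,thousand
US,male,total,2005,1199,thousand
US,male,total,2015,1325,thousand
UK,male,attributable,1955,90,thousand
UK,male,attributable,1965,126,thousand
UK,male,attributable,1975,142,thousand
UK,male,attributable,1985,125,thousand
UK,male,attributable,1995,95,thousand
UK,male,attributable,2005,67,thousand
UK,male,attributable,2015,55,thousand
UK,male,total,1955,303,thousand
UK,male,total,1965,324,thousand
UK,male,total,1975,337,thousand
UK,male,total,1985,325,thousand
UK,male,total,1995,308,thousand
UK,male,total,2005,279,thousand
UK,male,total,2015,264,thousand
Canada,male,attributable,1955,8.8,thousand
Canada,male,attributable,1965,17,thousand
Canada,male,attributable,1975,26,thousand
Canada,male,attributable,1985,31,thousand
Canada,male,attributable,1995,33,thousand
Canada,male,attributable,2005,29,thousand
Canada,male,attributable,2015,28,thousand
Canada,male,total,1955,75,thousand
Canada,male,total,1965,87,thousand
Canada,male,total,1975,96,thousand
Canada,male,total,1985,100,thousand
Canada,male,total,1995,111,thousand
Canada,male,total,2005,116,thousand
Canada,male,total,2015,129,thousand
US,female,attributable,1955,1.4,thousand
US,female,attributable,1965,19,thousand
US,female,attributable,1975,79,thousand
US,female,attributable,1985,169,thousand
US,female,attributable,1995,272,thousand
US,female,attributable,2005,302,thousand
US,female,attributable,2015,302,thousand
US,female,total,1955,663,thousand
US,female,total,1965,795,thousand
US,female,total,1975,858,thousand
US,female,total,1985,983,thousand
US,female,total,1995,1135,thousand
US,female,total,2005,1229,thousand
US,female,total,2015,1288,thousand
UK,female,attributable,1955,12,thousand
UK,female,attributable,1965,24,thousand
UK,female,attributable,1975,43,thousand
UK,female,attributable,1985,59,thousand
UK,female,attributable,1995,69,thousand
UK,female,attributable,2005,66,thousand
UK,female,attributable,2015,60,thousand
UK,female,total,1955,285,thousand
UK,female,total,1965,307,thousand
UK,female,total,1975,331,thousand
UK,female,total,1985,331,thousand
UK,female,total,1995,332,thousand
UK,female,total,2005,306,thousand
UK,female,total,2015,277,thousand
Canada,female,attributable,1955,0,thousand
Canada,female,attributable,1965,0.7,thousand
Canada,female,attributable,1975,4.2,thousand
Canada,female,attributable,1985,11,thousand
Canada,female,attributable,1995,20,thousand
Canada,female,attributable,2005,26,thousand
Canada,female,attributable,2015,30,thousand
Canada,female,total,1955,54,thousand
Canada,female,total,1965,61,thousand
Canada,female,total,1975,70,thousand
Canada,female,total,1985,80,thousand
Canada,female,total,1995,99,thousand
Canada,female,total,2005,113,thousand
Canada,female,total,2015,126,thousand
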