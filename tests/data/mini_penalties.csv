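patient_id,diagnosis,day,quadratic,one_sided,n_hours
NOpC0000,NOpC,day1,0.125201744777,0.166666666667,24
NOpC0001,NOpC,day1,0.116542095468,0.25,24
NOpC0001,NOpC,day2,0.0946356143177,0.0416666666667,24
OpC0000,OpC,day1,0.141639178805,0.25,24
OpC0000,OpC,day2,0.102489137381,0.125,24
OpC0001,OpC,day1,0.120688650433,0.125,24
NOpG0000,NOpG,day1,0.0512683407955,0,24
NOpG0001,NOpG,day1,0.0637068996555,0.0416666666667,24
NOpG0001,NOpG,day2,0.0494784400378,0.0833333333333,24
OpG0000,OpG,day1,0.0832217524245,0.125,24
OpG0000,OpG,day2,0.0582510996857,0.125,24
OpG0001,OpG,day1,0.0898724475891,0.0833333333333,24
NOpO0000,NOpO,day1,0.103019744525,0.0833333333333,24
NOpO0001,NOpO,day1,0.0812903366132,0.0833333333333,24
NOpO0001,NOpO,day2,0.0545590946642,0.0416666666667,24
NOpO0001,NOpO,day3,0.0362611004143,0.0416666666667,24
NOpO0001,NOpO,day4plus,0.0223100026414,0,11
OpO0000,OpO,day1,0.0888194152784,0.0416666666667,24
OpO0000,OpO,day2,0.0503964063158,0.0416666666667,24
OpO0001,OpO,day1,0.0910208184674,0.166666666667,24
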