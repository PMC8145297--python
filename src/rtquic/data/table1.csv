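subject_id,age_months,genotype,tissue,endpoint,tested_to
3M-#1,3,transgenic,brain,ND,-5
3M-#2,3,transgenic,brain,ND,-5
3M-#3,3,transgenic,brain,ND,-5
3M-Con,3,non_carrier,brain,ND,-3
3M-#1,3,transgenic,colon,1e-4,-5
3M-#2,3,transgenic,colon,1e-3,-4
3M-#3,3,transgenic,colon,1e-3,-4
3M-Con,3,non_carrier,colon,ND,-3
6M-#1,6,transgenic,brain,ND,-5
6M-#2,6,transgenic,brain,1e-3,-5
6M-#3,6,transgenic,brain,ND,-5
6M-Con,6,non_carrier,brain,ND,-3
6M-#1,6,transgenic,colon,1e-5,-5
6M-#2,6,transgenic,colon,1e-5,-5
6M-#3,6,transgenic,colon,1e-3,-5
6M-Con,6,non_carrier,colon,ND,-3
12M-#1,12,transgenic,brain,1e-5,-8
12M-#2,12,transgenic,brain,1e-8,-8
12M-#3,12,transgenic,brain,1e-5,-8
12M-Con,12,non_carrier,brain,ND,-3
12M-#1,12,transgenic,colon,1e-5,-6
12M-#2,12,transgenic,colon,1e-5,-6
12M-#3,12,transgenic,colon,1e-5,-6
12M-Con,12,non_carrier,colon,ND,-3
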