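subject_id,age_months,genotype,tissue,endpoint,tested_to
1M-#1,1,transgenic,colon,ND,-4
1M-#2,1,transgenic,colon,ND,-4
1M-#3,1,transgenic,colon,ND,-4
1M-Con,1,non_carrier,colon,ND,-4
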