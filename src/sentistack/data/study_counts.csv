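school_id,year,n_negative,n_nonnegative
UCLA,2019,6121,10773
UCLA,2020,7680,11034
UCSD,2019,6502,11000
UCSD,2020,6696,10650
UCB,2019,6650,10023
UCB,2020,7699,10495
UMich,2019,4126,8398
UMich,2020,6922,7957
Harvard,2019,935,1958
Harvard,2020,1138,2416
Columbia,2019,1686,3345
Columbia,2020,3423,5914
Dartmouth,2019,308,966
Dartmouth,2020,284,942
ND,2019,395,1184
ND,2020,4232,3718
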