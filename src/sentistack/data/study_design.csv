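school_id,funding,location,in_person,messages_2019,messages_2020
UCLA,public,large,no,16894,18714
UCSD,public,large,yes,17502,17346
UCB,public,small,no,16673,18194
UMich,public,small,yes,12524,14879
Harvard,private,large,no,2893,3554
Columbia,private,large,yes,5031,9337
Dartmouth,private,small,no,1274,1226
ND,private,small,yes,1579,7950
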