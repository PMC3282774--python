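study_id,author,year,country,ethnicity,method,case_GG,case_GC,case_CC,ctrl_GG,ctrl_GC,ctrl_CC
Hu2008,Hu,2008,China,Asian,PCR-RFLP,165,515,329,180,551,362
Hoffman2009,Hoffman,2009,USA,Mix,MassARRAY,234,176,29,273,178,27
Pastrello2010,Pastrello,2010,Italy,European,Sequencing,53,30,5,90,59,6
Catucci2010-Italy,Catucci,2010,Italy,European,PCR-RFLP,409,286,59,650,520,73
Catucci2010-Germany,Catucci,2010,Germany,European,PCR-RFLP,451,304,50,536,318,50
Garcia2011,Garcia,2011,France,European,Taqman,676,388,66,352,220,24
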