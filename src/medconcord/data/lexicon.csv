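code,code_system,name,med_class,spectrum
1001,RXNORM,penicillin,penicillins,narrow
1002,RXNORM,amoxicillin,penicillins,narrow
1003,RXNORM,dicloxacillin,penicillins,narrow
1004,RXNORM,amoxicillin-clavulanate,penicillin_combinations,broad
1005,RXNORM,ampicillin-sulbactam,penicillin_combinations,broad
1006,RXNORM,cephalexin,cephalosporins_1st_gen,broad
1007,RXNORM,cefadroxil,cephalosporins_1st_gen,broad
1008,RXNORM,cefuroxime,cephalosporins_2nd_gen,broad
1009,RXNORM,cefprozil,cephalosporins_2nd_gen,broad
1010,RXNORM,cefdinir,cephalosporins_3rd_gen,broad
1011,RXNORM,cefixime,cephalosporins_3rd_gen,broad
1012,RXNORM,ceftriaxone,cephalosporins_3rd_gen,broad
1013,RXNORM,azithromycin,macrolides,broad
1014,RXNORM,erythromycin,macrolides,broad
1015,RXNORM,clarithromycin,macrolides,broad
1016,RXNORM,sulfamethoxazole-trimethoprim,sulfonamides,broad
1017,RXNORM,doxycycline,tetracyclines,broad
1018,RXNORM,minocycline,tetracyclines,broad
1019,RXNORM,ciprofloxacin,fluoroquinolones,broad
1020,RXNORM,levofloxacin,fluoroquinolones,broad
1021,RXNORM,clindamycin,lincosamides,broad
1022,RXNORM,nitrofurantoin,nitrofurans,broad
1023,RXNORM,metronidazole,nitroimidazoles,broad
1024,RXNORM,vancomycin,glycopeptides,broad
1025,RXNORM,linezolid,oxazolidinones,broad
1026,RXNORM,neomycin,aminoglycosides,broad
55555-0001-01,NDC,penicillin,penicillins,narrow
55555-0002-01,NDC,amoxicillin,penicillins,narrow
55555-0002-02,NDC,amoxicillin,penicillins,narrow
55555-0003-01,NDC,dicloxacillin,penicillins,narrow
55555-0004-01,NDC,amoxicillin-clavulanate,penicillin_combinations,broad
55555-0005-01,NDC,ampicillin-sulbactam,penicillin_combinations,broad
55555-0006-01,NDC,cephalexin,cephalosporins_1st_gen,broad
55555-0007-01,NDC,cefadroxil,cephalosporins_1st_gen,broad
55555-0008-01,NDC,cefuroxime,cephalosporins_2nd_gen,broad
55555-0009-01,NDC,cefprozil,cephalosporins_2nd_gen,broad
55555-0010-01,NDC,cefdinir,cephalosporins_3rd_gen,broad
55555-0011-01,NDC,cefixime,cephalosporins_3rd_gen,broad
55555-0012-01,NDC,ceftriaxone,cephalosporins_3rd_gen,broad
55555-0013-01,NDC,azithromycin,macrolides,broad
55555-0013-02,NDC,azithromycin,macrolides,broad
55555-0014-01,NDC,erythromycin,macrolides,broad
55555-0015-01,NDC,clarithromycin,macrolides,broad
55555-0016-01,NDC,sulfamethoxazole-trimethoprim,sulfonamides,broad
55555-0017-01,NDC,doxycycline,tetracyclines,broad
55555-0018-01,NDC,minocycline,tetracyclines,broad
55555-0019-01,NDC,ciprofloxacin,fluoroquinolones,broad
55555-0020-01,NDC,levofloxacin,fluoroquinolones,broad
55555-0021-01,NDC,clindamycin,lincosamides,broad
55555-0022-01,NDC,nitrofurantoin,nitrofurans,broad
55555-0023-01,NDC,metronidazole,nitroimidazoles,broad
55555-0024-01,NDC,vancomycin,glycopeptides,broad
55555-0025-01,NDC,linezolid,oxazolidinones,broad
55555-0026-01,NDC,neomycin,aminoglycosides,broad
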