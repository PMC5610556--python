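species_group,species,authority,endemic,exotic,status,exclusion_reason,comments
angulinode,smithi,"Mayr, 1879",no,no,valid,,
bicarinatum,bicarinatum,"(Nylander, 1846)",no,no,valid,,Cosmopolitan tramp; native range likely Southeast Asia; native-vs-exotic status in India unresolved without population genetic analyses
bicarinatum,indicum,"Forel, 1913",no,no,valid,,
bicarinatum,pacificum,"Mayr, 1870",no,no,valid,,Native range unknown; classification as exotic problematic; identification in the Indomalayan region very difficult
bicarinatum,petiolatum,"Sheela & Narendran, 1998",yes,no,valid,,
bicarinatum,scabrum,"Mayr, 1879",no,no,valid,,
caespitum,nursei,"Bingham, 1903",no,no,valid,,Record from Kerala extremely dubious
ciliatum,shivalikense,"Bharti & Kumar, 2012",yes,no,valid,,
fergusoni,fergusoni,"Forel, 1902",yes,no,valid,,
inglebyi,elisabethae,"Forel, 1904",yes,no,valid,,
inglebyi,inglebyi,"Forel, 1902",yes,no,valid,,Dubious records from Borneo and China (Yunnan)
inglebyi,myops,"Bolton, 1977",yes,no,valid,,
inglebyi,triangulatum,"Bharti & Kumar, 2012",yes,no,valid,,
inglebyi,jarawa,,yes,no,valid,,New species from Havelock Island (Andaman Islands)
melleum,mayri,"(Forel, 1912)",no,no,valid,,
melleum,wroughtoni,"(Forel, 1902)",no,no,valid,,
mixtum,malabarense,"Sheela & Narendran, 1998",yes,no,valid,,
mixtum,mixtum,"Forel, 1902",yes,no,valid,,Record from Borneo dubious
mixtum,rugigaster,"Bolton, 1977",yes,no,valid,,
mixtum,sentosum,"Sheela & Narendran, 1998",yes,no,valid,,
obesum,coonoorense,"Forel, 1902",yes,no,valid,,
obesum,decamerum,"(Forel, 1902)",yes,no,valid,,
obesum,lanuginosum,"Mayr, 1870",no,no,valid,,
obesum,obesum,"André, 1887",no,no,valid,,
obesum,rossi,"(Bolton, 1976)",yes,no,valid,,
simillimum,caldarium,"(Roger, 1857)",no,yes,valid,,Panglobal tramp of Afrotropical origin
simillimum,simillimum,"(Smith, 1851)",no,yes,valid,,Panglobal tramp of Afrotropical origin
tonganum,barryi,"Mathew, 1981",yes,no,valid,,
tonganum,christiei,"Forel, 1902",yes,no,valid,,
tonganum,salvatum,"Forel, 1902",yes,no,valid,,
tonganum,krishnani,,yes,no,valid,,New species from Havelock Island (Andaman Islands)
tortuosum,belgaense,"Forel, 1902",yes,no,valid,,
tortuosum,keralense,"Sheela & Narendran, 1998",yes,no,valid,,
tortuosum,pilosum,"Emery, 1893",yes,no,valid,,Record from Zhejiang dubious
tortuosum,urbanii,"Bolton, 1977",yes,no,valid,,
tortuosum,tortuosum,"Roger, 1863",no,no,valid,,
tortuosum,yerburyi,"Forel, 1902",yes,no,valid,,Record from Yunnan dubious
walshi,cordatum,"Sheela & Narendran, 1998",yes,no,valid,,
walshi,kheperra,"(Bolton, 1976)",no,no,valid,,
walshi,walshi,"(Forel, 1890)",no,no,valid,,
unclear,beesoni,"(Mukerjee, 1934)",yes,no,valid,,Initially described in Myrmica; species group unknown
unclear,meghalayense,"Bharti, 2011",yes,no,valid,,Originally placed in the bicarinatum group but that placement is dubious; replacement name for the junior homonym browni
tonganum,tonganum,"Mayr, 1870",no,no,excluded,Indian records are based on a misidentification; the material reported under this name is actually salvatum,Widespread in tropical Asia; kept in the species key to facilitate future identifications
unclear,browni,"Mathew & Tiwari, 2000",no,no,excluded,Junior primary homonym of an earlier browni; replaced by meghalayense,
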