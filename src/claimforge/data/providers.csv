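npi,org_name,taxonomy,street,city,state,zip
1548083421,"HSA GLENWOOD, LLC",282N00000X,1200 N BRAND BLVD,GLENDALE,CA,91203
2719492367,RED ROCK SURGICAL CENTER,282E00000X,2005 MAIN ST,SPOKANE,WA,99201
1287382737,PRAIRIE SURGICAL CENTER,282N00000X,7070 RIVER RD,TAMPA,FL,33602
1080013216,EASTBROOK SURGICAL CENTER,282N00000X,6562 UNIVERSITY BLVD,AUSTIN,TX,78701
2613277179,BLUE RIDGE REGIONAL HOSPITAL,282N00000X,5444 HOSPITAL WAY,DULUTH,MN,55802
2617114360,GOLDEN VALLEY SURGICAL CENTER,314000000X,4651 HOSPITAL WAY,PORTLAND,OR,97205
1184403701,HIGHLAND SURGICAL CENTER,282E00000X,402 E 5TH ST,DULUTH,MN,55802
1290156730,"ST VINCENT COMMUNITY HOSPITAL, INC",282N00000X,4763 E 5TH ST,PORTLAND,OR,97205
1274786114,RED ROCK REGIONAL HOSPITAL,282NC0060X,6150 OAK AVE,BOISE,ID,83702
1020619361,"SILVER LAKE COMMUNITY HOSPITAL, INC",283X00000X,4115 W CENTRAL AVE,AUSTIN,TX,78701
1716970870,"CEDAR GROVE COMMUNITY HOSPITAL, INC",283Q00000X,9218 UNIVERSITY BLVD,PHOENIX,AZ,85004
1363729975,OAKMONT REGIONAL HOSPITAL,283Q00000X,2842 N BRAND BLVD,COLUMBUS,OH,43215
2966694012,"MAPLEWOOD COMMUNITY HOSPITAL, INC",283Q00000X,8739 RIVER RD,OMAHA,NE,68102
2831594355,"PRAIRIE COMMUNITY HOSPITAL, INC",261QE0002X,1567 E 5TH ST,PHOENIX,AZ,85004
1380207153,"EASTBROOK COMMUNITY HOSPITAL, INC",282NC0060X,6505 MAIN ST,DENVER,CO,80203
2596345720,"RIVERSIDE HEALTH SYSTEM, LLC",314000000X,1455 HOSPITAL WAY,OMAHA,NE,68102
2575355203,SIERRA VISTA MEDICAL CENTER,282N00000X,4223 ELM ST,DENVER,CO,80203
2418575827,"SUMMIT COMMUNITY HOSPITAL, INC",261QE0002X,6981 MEDICAL PARK DR,SPOKANE,WA,99201
1566347799,SUMMIT MEDICAL CENTER,324500000X,7827 MEDICAL PARK DR,COLUMBUS,OH,43215
2473008250,NORTHGATE REGIONAL HOSPITAL,283Q00000X,5558 MEDICAL PARK DR,SPOKANE,WA,99201
2621234246,SIERRA VISTA REGIONAL HOSPITAL,261QE0002X,2343 ELM ST,TAMPA,FL,33602
1289561874,GOLDEN VALLEY REHABILITATION HOSPITAL,283X00000X,2376 E 5TH ST,OMAHA,NE,68102
1499622045,"FAIRVIEW COMMUNITY HOSPITAL, INC",283Q00000X,7762 E 5TH ST,DENVER,CO,80203
2082303340,OAKMONT MEDICAL CENTER,324500000X,7693 OAK AVE,OMAHA,NE,68102
2207785272,BAYSHORE REGIONAL HOSPITAL,282N00000X,1394 MAIN ST,OMAHA,NE,68102
1944041569,HIGHLAND REGIONAL HOSPITAL,283Q00000X,3568 OAK AVE,TUCSON,AZ,85701
2277111268,GLENWOOD REHABILITATION HOSPITAL,324500000X,7585 RIVER RD,RALEIGH,NC,27601
2139805941,HARBORVIEW REGIONAL HOSPITAL,314000000X,7232 W CENTRAL AVE,BOISE,ID,83702
1222438677,SILVER LAKE MEDICAL CENTER,314000000X,3420 OAK AVE,DENVER,CO,80203
2918299415,"BAYSHORE HEALTH SYSTEM, LLC",261QE0002X,5298 HOSPITAL WAY,SPOKANE,WA,99201
2104450640,"LAKESIDE COMMUNITY HOSPITAL, INC",283Q00000X,7350 ELM ST,DULUTH,MN,55802
2106885405,GOLDEN VALLEY REGIONAL HOSPITAL,282NC0060X,5771 N BRAND BLVD,TUCSON,AZ,85701
1274876741,FAIRVIEW MEDICAL CENTER,261QE0002X,5420 E 5TH ST,DENVER,CO,80203
2963421245,GRANITE PEAK REHABILITATION HOSPITAL,283X00000X,3107 N BRAND BLVD,PORTLAND,OR,97205
2854649441,NORTHGATE REHABILITATION HOSPITAL,261QE0002X,5862 W CENTRAL AVE,PORTLAND,OR,97205
2897174688,"RED ROCK HEALTH SYSTEM, LLC",283X00000X,2912 MEDICAL PARK DR,PHOENIX,AZ,85004
1836648786,"PIONEER COMMUNITY HOSPITAL, INC",283X00000X,9003 ELM ST,PHOENIX,AZ,85004
1243993056,CEDAR GROVE SURGICAL CENTER,324500000X,8092 ELM ST,TAMPA,FL,33602
1877963334,WESTFIELD REHABILITATION HOSPITAL,282E00000X,8264 UNIVERSITY BLVD,TUCSON,AZ,85701
2991835663,LAKESIDE REGIONAL HOSPITAL,314000000X,7996 E 5TH ST,DULUTH,MN,55802
1154042794,SUMMIT REHABILITATION HOSPITAL,282NC0060X,2708 N BRAND BLVD,GLENDALE,CA,91203
2678970866,"CEDAR GROVE HEALTH SYSTEM, LLC",261QE0002X,8151 RIVER RD,PHOENIX,AZ,85004
1920977406,CEDAR GROVE REGIONAL HOSPITAL,282N00000X,4751 E 5TH ST,BOISE,ID,83702
2407061532,"WESTFIELD COMMUNITY HOSPITAL, INC",282NC0060X,4710 E 5TH ST,TUCSON,AZ,85701
1395481579,FAIRVIEW SURGICAL CENTER,283X00000X,4889 OAK AVE,COLUMBUS,OH,43215
2235941145,GRANITE PEAK SURGICAL CENTER,324500000X,5744 MEDICAL PARK DR,BOISE,ID,83702
1867894069,HIGHLAND REHABILITATION HOSPITAL,282E00000X,5643 MEDICAL PARK DR,COLUMBUS,OH,43215
2912302777,GLENWOOD REGIONAL HOSPITAL,314000000X,8742 HOSPITAL WAY,OMAHA,NE,68102
1353225075,SUMMIT SURGICAL CENTER,282N00000X,5438 N BRAND BLVD,DULUTH,MN,55802
2087084580,LAKESIDE REHABILITATION HOSPITAL,283X00000X,7474 ELM ST,DULUTH,MN,55802
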