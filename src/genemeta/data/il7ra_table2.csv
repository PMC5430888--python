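study_id,first_author,year,snp_id,case_mm,case_mw,case_ww,ctrl_mm,ctrl_mw,ctrl_ww,area,risk_allele
Zhang2005,Zhang,2005,rs3194051,54,235,378,23,230,305,Sweden,G
Gregory2007,Gregory,2007,rs3194051,46,157,235,33,198,247,USA,G
Lundmark2007,Lundmark,2007,rs3194051,149,657,979,152,982,1430,Nordic countries,G
ODoherty1_2008,O'Doherty(1),2008,rs3194051,18,85,105,30,163,220,USA,G
ODoherty2_2008,O'Doherty(2),2008,rs3194051,31,178,254,36,206,289,Northern Ireland,G
Akkad2009,Akkad,2009,rs3194051,102,511,666,63,346,448,Germany,G
Bahlo2009,Bahlo,2009,rs3194051,152,868,1235,160,897,1251,Australia/New Zealand,G
Kallio2009,Kallio,2009,rs3194051,13,76,108,25,158,250,Finland,G
Zhang2005,Zhang,2005,rs987107,53,186,289,34,228,301,Sweden,T
Gregory2007,Gregory,2007,rs987107,46,157,235,33,196,250,USA,T
Lundmark2007,Lundmark,2007,rs987107,152,651,976,157,991,1417,Nordic countries,T
ODoherty1_2008,O'Doherty(1),2008,rs987107,17,83,107,29,160,224,USA,T
ODoherty2_2008,O'Doherty(2),2008,rs987107,31,178,253,35,202,290,Northern Ireland,T
Jager2013,Jaeger,2013,rs987107,48,194,242,19,121,171,Germany,T
Teutsch2003,Teutsch,2003,rs11567686,19,79,78,18,75,83,Australia,G
Broux2010,Broux,2010,rs11567686,8,29,28,2,12,19,Belgium,G
Hoe2010,Hoe,2010,rs11567686,102,370,338,112,442,437,Australia,G
Heidari2011,Heidari,2011,rs11567686,18,51,31,16,47,37,Iran,G
Haj2015,Haj,2015,rs11567686,49,99,54,58,102,84,Iran,G
Teutsch2003,Teutsch,2003,rs11567685,7,37,57,8,43,39,Australia,C
Booth2005,Booth,2005,rs11567685,28,134,201,8,84,90,Australia,C
Akkad2009,Akkad,2009,rs11567685,103,507,694,65,356,468,Germany,C
Broux2010,Broux,2010,rs11567685,6,28,31,3,14,16,Belgium,C
Hoe2010,Hoe,2010,rs11567685,56,313,441,71,389,531,Australia,C
Heidari2011,Heidari,2011,rs11567685,9,38,53,8,44,48,Iran,C
Ibayyan2014,Ibayyan,2014,rs11567685,4,59,137,10,78,112,Jordan,C
Haj2015,Haj,2015,rs11567685,19,80,120,28,87,143,Iran,C
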