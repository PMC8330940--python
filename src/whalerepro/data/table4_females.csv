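whale_id,feeding_group,age_class,reproductive_status,progesterone_ng_g,year_sampled,month_sampled,year_resight,resight_with_calf
860,PCFG,Immature,Immature,3.5,2004,September,2005,False
1512,PCFG,Immature,Immature,2,2013,October,2014,False
1559,PCFG,Immature,Immature,2.3,2015,October,2016,False
1622,PCFG,Immature,Immature,0.7,2015,October,2016,False
1736,PCFG,Immature,Immature,2.7,2015,October,2016,False
1822,PCFG,Immature,Immature,1.7,2015,October,2016,False
67,PCFG,Adult,Lactating,3.6,2004,August,2005,False
178,PCFG,Adult,Lactating,3.3,2013,July,2014,False
372,PCFG,Adult,Lactating,1.7,2015,August,2016,False
525,PCFG,Adult,Lactating,2.0,2015,October,,False
719,PCFG,Adult,Lactating,1.5,2015,October,2016,False
827,PCFG,Adult,Lactating,1.5,2015,September,2018,False
92,PCFG,Adult,Pregnant,14.8,2012,August,2013,True
193,PCFG,Adult,Pregnant,21.2,2015,October,2016,True
196,PCFG,Adult,Pregnant,11.2,2015,October,2016,True
280,PCFG,Adult,Pregnant,30.8,2015,October,2016,True
30,PCFG,Adult,Unknown,17.3,2015,October,2016,False
94,PCFG,Adult,Unknown,1.5,2010,October,2011,False
127,PCFG,Adult,Unknown,0.7,2010,September,2011,False
141,PCFG,Adult,Unknown,9.1,2005,July,2006,False
143,PCFG,Adult,Unknown,7.5,2015,October,2016,False
192,PCFG,Adult,Unknown,20.8,2011,August,2012,False
204,PCFG,Adult,Unknown,0.8,2010,July,2011,False
231,PCFG,Adult,Unknown,3.5,2014,September,2017,False
238,PCFG,Adult,Unknown,1.3,2015,October,2017,False
242,PCFG,Adult,Unknown,27.3,2015,September,2018,False
302,PCFG,Adult,Unknown,0.9,2010,September,2011,False
396,PCFG-NPS,Adult,Unknown,0.9,2010,September,2011,False
531,NPS,Adult,Unknown,20.4,2016,March,2018,False
532,PCFG,Adult,Unknown,5.8,2012,July,2013,False
554,PCFG,Adult,Unknown,4.4,2015,October,2016,False
629,PCFG,Adult,Unknown,1.9,2015,October,,False
637,PCFG,Adult,Unknown,48.9,2013,August,2018,False
657,PCFG,Adult,Unknown,1.2,2015,October,2016,False
659,PCFG,Adult,Unknown,1.8,2012,July,2014,False
668,PCFG,Adult,Unknown,2.7,2012,July,2014,False
698,PCFG,Adult,Unknown,8.5,2015,September,2016,False
759,PCFG,Adult,Unknown,2.2,2015,October,,False
760,PCFG,Adult,Unknown,3.0,2015,September,,False
872,PCFG,Adult,Unknown,4.8,2013,August,2015,False
900,PCFG,Adult,Unknown,11.4,2015,October,2018,False
1067,PCFG,Adult,Unknown,1.6,2015,September,,False
826,PCFG,Unknown,Unknown,0.8,2010,September,2016,False
842,PCFG,Unknown,Unknown,2.7,2004,September,2005,False
1053,PCFG,Unknown,Unknown,19.7,2008,October,2012,False
1059,PCFG,Unknown,Unknown,61.7,2008,October,2009,False
1118,PCFG,Unknown,Unknown,3.1,2015,September,2016,False
1172,PCFG,Unknown,Unknown,2.2,2012,August,2013,False
1201,PCFG,Unknown,Unknown,0.6,2012,July,2013,False
1551,PCFG,Unknown,Unknown,1.7,2012,August,2013,False
1597,ENP,Unknown,Unknown,2.5,2013,October,,False
1598,ENP,Unknown,Unknown,29.1,2013,October,2014,False
1600,ENP,Unknown,Unknown,12.2,2013,September,,False
1602,ENP,Unknown,Unknown,8.4,2013,September,,False
1646,PCFG,Unknown,Unknown,1.7,2015,October,,False
1681,PCFG,Unknown,Unknown,21.3,2014,September,,False
1868,PCFG,Unknown,Unknown,1.1,2015,September,2016,False
1870,ENP,Unknown,Unknown,5.1,2015,July,,False
1872,ENP,Unknown,Unknown,4.1,2015,August,,False
1881,ENP,Unknown,Unknown,4.2,2015,August,,False
1890,ENP,Unknown,Unknown,1.3,2015,September,,False
1899,ENP,Unknown,Unknown,1.4,2015,October,,False
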