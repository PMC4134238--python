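variable,units,mean,sd,min,max
LONG,deg,-105.6,0.690,-107.2,-104.1
LAT,deg,24.5,1.066,22.4,26.8
ELEV,m,2239.0,506.1,390.1,3156.0
MAT,degC,13.5,3.8,8.3,26.2
MAP,mm,916.8,218.7,444.6,1450.0
GSP,mm,694.3,143.3,378.0,1033.0
MTCM,degC,8.3,4.0,2.9,21.4
MMIN,degC,-0.867,4.6,-6.8,12.0
MTWM,degC,18.1,3.8,12.6,30.5
MMAX,degC,26.5,3.4,20.6,40.2
SDAY,julian day,112,49,1,182
FDAY,julian day,303,29,251,365
FFP,days,192,76,79,365
DD5,degree-days,3200,1317,2725,7640
GSDD5,degree-days,2373,1537,1780,7551
D100,julian day,36,19,36,84
DD0,degree-days,8,11,1,65
MMINDD0,degree-days,503,367,484,1323
AAI,days^0.5/mm,0.064,0.020,0.060,0.154
NIP,trees,70,43,62,348
v0,,6.5,2.9,6,17
v2,,3.5,1.6,3.3,9.7
vinf,,2.42,0.98,2.30,6.92
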