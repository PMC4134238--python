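response,covariate,tau,r2,a,b,c,d,e
v0,MAT,0.9,0.68,-0.0009,0.0628,-1.6188,17.2090,-53.4731
v0,MAT,0.5,0.36,-0.0009,0.0618,-1.5001,15.0798,-45.9928
v0,MAT,0.1,0.76,-0.0005,0.0308,-0.7001,6.3320,-15.0739
v0,MTWM,0.9,0.70,-0.0007,0.0678,-2.3462,34.2400,-168.4842
v0,MTWM,0.5,0.46,-0.0013,0.1176,-3.7609,51.5186,-247.7348
v0,MTWM,0.1,0.79,-0.0007,0.0587,-1.8170,23.9195,-109.1866
v0,MMAX,0.9,0.80,-0.0014,0.1764,-8.2776,168.7058,-1252.0169
v0,MMAX,0.5,0.43,,0.0057,-0.4649,12.0452,-92.7230
v0,MMAX,0.1,0.81,-0.0006,0.0753,-3.2486,60.8045,-411.7345
v0,AAI,0.9,0.66,-571021.2704,195722.2198,-23593.7069,1132.4081,-7.6657
v0,AAI,0.5,0.48,-453491.3979,158284.4650,-19007.7266,860.1545,-4.8716
v0,AAI,0.1,0.85,-426868.9341,131061.4899,-13434.8946,476.2212,0.2906
v0,NIP,0.9,0.90,-1.7209E-08,1.1462E-05,-2.5805E-03,0.24392,2.67529
v0,NIP,0.5,0.61,-4.7616E-09,3.8079E-06,-1.1208E-03,0.14230,1.56533
v0,NIP,0.1,0.87,-2.4871E-09,1.5035E-06,-0.00037,0.06309,0.60922
v2,MMAX,0.9,0.67,-0.0010,0.1180,-5.3449,105.9564,-769.6654
v2,MMAX,0.5,0.37,-0.0005,0.0627,-2.8916,58.0009,-423.3663
v2,MMAX,0.1,0.75,-0.0003,0.0355,-1.5887,30.9829,-220.1202
v2,AAI,0.9,0.64,-413660.0818,143466.7997,-17458.6761,855.7508,-8.3143
v2,AAI,0.5,0.36,-149515.0681,53535.0264,-6662.4690,310.2461,-0.7709
v2,AAI,0.1,0.81,-172936.4467,52569.6039,-5359.5093,191.1053,0.3302
vinf,AAI,0.9,0.65,-292007.5163,101441.4217,-12274.8255,594.2765,-5.7624
vinf,AAI,0.5,0.31,-50472.4434,17865.9822,-2180.6198,91.9919,1.4579
vinf,AAI,0.1,0.79,-115122.9857,36829.1202,-4014.9091,163.7877,-0.5152
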