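response,tau,r2,a,b,c
v0,0.9,0.504,0.00223,-0.14530,11.77380
v0,0.5,0.431,0.00286,-0.32059,12.25270
v0,0.1,0.834,0.00270,-0.27780,8.18577
v2,0.9,0.578,0.00039,-0.10047,6.87903
v2,0.5,0.353,0.00139,-0.15818,6.20199
v2,0.1,0.754,0.00078,-0.09694,3.52116
vinf,0.9,0.551,0.00093,-0.06663,4.64010
vinf,0.5,0.297,0.00075,-0.08048,3.70658
vinf,0.1,0.712,0.00035,-0.04265,2.13045
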