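group,variable,interval,mean,sd
responder,HR,T2-T1,2.4,5.5
nonresponder,HR,T2-T1,-1.9,3.6
responder,MAP,T2-T1,-7.3,8.5
nonresponder,MAP,T2-T1,-1.1,6.1
responder,HRRR,T2-T1,0.2,0.4
nonresponder,HRRR,T2-T1,-0.2,0.3
responder,Cdyn,T2-T1,3.1,5.4
nonresponder,Cdyn,T2-T1,4.1,2.7
responder,PIP,T2-T1,5.1,1.3
nonresponder,PIP,T2-T1,5.2,2.0
responder,CI,T2-T1,0.3,0.4
nonresponder,CI,T2-T1,-0.04,0.3
responder,SV,T2-T1,5.4,7.3
nonresponder,SV,T2-T1,0.0,4.4
responder,PPV,T2-T1,1.9,1.7
nonresponder,PPV,T2-T1,-0.7,1.8
responder,SVV,T2-T1,2.3,1.7
nonresponder,SVV,T2-T1,-0.5,1.8
responder,HR,T4-T3,0.2,6.9
nonresponder,HR,T4-T3,-1.0,4.1
responder,MAP,T4-T3,-1.3,7.4
nonresponder,MAP,T4-T3,0.9,6.9
responder,HRRR,T4-T3,-0.0,0.5
nonresponder,HRRR,T4-T3,-0.1,0.3
responder,Cdyn,T4-T3,-0.9,3.9
nonresponder,Cdyn,T4-T3,-1.3,1.5
responder,PIP,T4-T3,1.1,0.9
nonresponder,PIP,T4-T3,0.9,0.9
responder,CI,T4-T3,0.5,0.7
nonresponder,CI,T4-T3,0.1,0.3
responder,SV,T4-T3,14.1,8.5
nonresponder,SV,T4-T3,1.9,6.4
responder,PPV,T4-T3,-1.6,1.2
nonresponder,PPV,T4-T3,-0.6,1.4
responder,SVV,T4-T3,-1.6,1.2
nonresponder,SVV,T4-T3,-0.5,1.7
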