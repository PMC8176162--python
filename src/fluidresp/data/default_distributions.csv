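group,variable,time_point,mean,sd
responder,HR,T1,78.7,15.8
responder,HR,T2,81.1,15.5
responder,HR,T3,79.2,15.5
responder,HR,T4,79.4,14.6
nonresponder,HR,T1,72.6,9.9
nonresponder,HR,T2,70.6,8.2
nonresponder,HR,T3,69.3,8.8
nonresponder,HR,T4,68.3,9.7
responder,MAP,T1,91.9,15.3
responder,MAP,T2,84.6,17.0
responder,MAP,T3,84.4,13.4
responder,MAP,T4,83.1,13.5
nonresponder,MAP,T1,89.1,12.6
nonresponder,MAP,T2,88.0,13.9
nonresponder,MAP,T3,87.8,14.0
nonresponder,MAP,T4,88.7,10.6
responder,HRRR,T1,6.2,1.1
responder,HRRR,T2,6.3,1.2
responder,HRRR,T3,6.2,1.3
responder,HRRR,T4,6.2,1.1
nonresponder,HRRR,T1,5.8,0.9
nonresponder,HRRR,T2,5.6,0.8
nonresponder,HRRR,T3,5.5,0.8
nonresponder,HRRR,T4,5.4,0.8
responder,Cdyn,T1,23.8,6.1
responder,Cdyn,T2,26.9,7.9
responder,Cdyn,T3,23.9,7.7
responder,Cdyn,T4,23.0,6.0
nonresponder,Cdyn,T1,21.5,5.1
nonresponder,Cdyn,T2,25.6,4.8
nonresponder,Cdyn,T3,22.3,4.5
nonresponder,Cdyn,T4,21.0,4.2
responder,PIP,T1,18.2,3.5
responder,PIP,T2,23.2,2.7
responder,PIP,T3,17.4,3.2
responder,PIP,T4,18.5,3.5
nonresponder,PIP,T1,18.6,3.5
nonresponder,PIP,T2,23.8,2.3
nonresponder,PIP,T3,17.9,3.4
nonresponder,PIP,T4,18.8,3.3
responder,CI,T1,2.7,0.6
responder,CI,T2,2.9,0.7
responder,CI,T3,2.9,0.7
responder,CI,T4,3.4,0.9
nonresponder,CI,T1,3.0,1.0
nonresponder,CI,T2,3.0,0.9
nonresponder,CI,T3,2.9,0.9
nonresponder,CI,T4,3.1,0.8
responder,SV,T1,58.3,12.9
responder,SV,T2,63.7,16.8
responder,SV,T3,63.1,17.2
responder,SV,T4,77.2,16.8
nonresponder,SV,T1,71.5,19.3
nonresponder,SV,T2,71.5,19.7
nonresponder,SV,T3,72.3,17.7
nonresponder,SV,T4,74.3,17.5
responder,PPV,T1,5.4,1.8
responder,PPV,T2,7.3,2.9
responder,PPV,T3,5.8,2.4
responder,PPV,T4,4.2,2.1
nonresponder,PPV,T1,5.5,2.1
nonresponder,PPV,T2,4.8,1.7
nonresponder,PPV,T3,5.6,1.8
nonresponder,PPV,T4,5.0,1.4
responder,SVV,T1,5.5,2.4
responder,SVV,T2,7.8,3.3
responder,SVV,T3,5.7,2.4
responder,SVV,T4,4.2,1.9
nonresponder,SVV,T1,5.0,2.3
nonresponder,SVV,T2,4.4,2.4
nonresponder,SVV,T3,5.2,2.5
nonresponder,SVV,T4,4.7,2.3
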