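sex,gene,region,age,source,q_percent,lo,hi
male,MLH1,Europe,30,retrospective,0.9,0.4,1.8
male,MLH1,Europe,40,retrospective,2.6,1.2,5.2
male,MLH1,Europe,50,retrospective,8.1,5.0,14
male,MLH1,Europe,60,retrospective,21,15,29
male,MLH1,Europe,70,retrospective,36,27,48
male,MLH1,Europe,30,prospective,2.7,1.0,7.0
male,MLH1,Europe,40,prospective,14.2,10.2,19.6
male,MLH1,Europe,50,prospective,30.3,25.0,36.6
male,MLH1,Europe,60,prospective,44.3,37.9,51.2
male,MLH1,Europe,70,prospective,49.2,42.0,56.8
male,MLH1,All,25,retrospective,0.7,0.5,1.1
male,MLH1,All,30,retrospective,1.5,1.1,2.2
male,MLH1,All,40,retrospective,5.8,4.3,7.8
male,MLH1,All,50,retrospective,15,12,19
male,MLH1,All,60,retrospective,27,23,33
male,MLH1,All,70,retrospective,40,34,47
male,MLH1,All,30,prospective,3.5,1.6,7.6
male,MLH1,All,40,prospective,14.8,10.9,20.0
male,MLH1,All,50,prospective,32.1,27.0,38.0
male,MLH1,All,60,prospective,45.1,39.2,51.4
male,MLH1,All,70,prospective,51.9,45.2,58.9
male,MSH2,Europe,30,retrospective,0.7,0.4,1.5
male,MSH2,Europe,40,retrospective,2.2,1.1,4.2
male,MSH2,Europe,50,retrospective,6.7,4.1,11
male,MSH2,Europe,60,retrospective,16,12,22
male,MSH2,Europe,70,retrospective,28,21,38
male,MSH2,Europe,30,prospective,2.7,0.9,8.1
male,MSH2,Europe,40,prospective,8.9,5.3,14.6
male,MSH2,Europe,50,prospective,19.1,13.9,25.9
male,MSH2,Europe,60,prospective,34.1,26.8,42.8
male,MSH2,Europe,70,prospective,46.4,37.1,56.7
male,MSH2,All,25,retrospective,0.6,0.4,0.8
male,MSH2,All,30,retrospective,1.2,0.9,1.8
male,MSH2,All,40,retrospective,4.8,3.6,6.5
male,MSH2,All,50,retrospective,13,10,16
male,MSH2,All,60,retrospective,23,19,28
male,MSH2,All,70,retrospective,34,28,40
male,MSH2,All,30,prospective,3.7,1.6,8.8
male,MSH2,All,40,prospective,10.4,6.8,15.9
male,MSH2,All,50,prospective,21.3,16.3,27.4
male,MSH2,All,60,prospective,37.3,30.8,44.6
male,MSH2,All,70,prospective,49.6,41.5,58.4
male,MSH6,Europe,30,retrospective,0.4,0.1,1.3
male,MSH6,Europe,40,retrospective,1.2,0.4,3.8
male,MSH6,Europe,50,retrospective,3.6,1.4,9.7
male,MSH6,Europe,60,retrospective,8.1,4.1,17
male,MSH6,Europe,70,retrospective,14,7.8,24
male,MSH6,Europe,30,prospective,3.1,0.4,20.1
male,MSH6,Europe,40,prospective,4.6,1.1,18.5
male,MSH6,Europe,50,prospective,5.9,1.8,18.6
male,MSH6,Europe,60,prospective,11.5,5.5,23.5
male,MSH6,Europe,70,prospective,11.5,5.5,23.5
male,MSH6,All,25,retrospective,0.2,0.1,0.4
male,MSH6,All,30,retrospective,0.4,0.2,0.9
male,MSH6,All,40,retrospective,1.6,0.9,3.2
male,MSH6,All,50,retrospective,4.8,3.0,8.7
male,MSH6,All,60,retrospective,9.9,7.0,16
male,MSH6,All,70,retrospective,16,12,24
male,MSH6,All,30,prospective,2.8,0.4,18.3
male,MSH6,All,40,prospective,6.0,1.9,18.1
male,MSH6,All,50,prospective,7.1,2.6,18.7
male,MSH6,All,60,prospective,11.8,5.9,22.9
male,MSH6,All,70,prospective,13.4,7.0,24.9
male,PMS2,Europe,30,retrospective,0.1,0.1,0.1
male,PMS2,Europe,40,retrospective,0.3,0.3,0.3
male,PMS2,Europe,50,retrospective,1.0,0.9,1.1
male,PMS2,Europe,60,retrospective,3.5,2.8,4.1
male,PMS2,Europe,70,retrospective,7.6,5.7,9.7
male,PMS2,Europe,30,prospective,0,,
male,PMS2,Europe,40,prospective,0,,
male,PMS2,Europe,50,prospective,0,,
male,PMS2,Europe,60,prospective,12.1,3.2,40.3
male,PMS2,Europe,70,prospective,12.1,3.2,40.3
male,PMS2,All,25,retrospective,0.0,0.0,0.0
male,PMS2,All,30,retrospective,0.1,0.1,0.1
male,PMS2,All,40,retrospective,0.3,0.3,0.3
male,PMS2,All,50,retrospective,1.1,1.0,1.1
male,PMS2,All,60,retrospective,3.3,3.0,3.6
male,PMS2,All,70,retrospective,7.1,6.3,8.1
male,PMS2,All,30,prospective,0,,
male,PMS2,All,40,prospective,0,,
male,PMS2,All,50,prospective,0,,
male,PMS2,All,60,prospective,10.7,2.8,36.5
male,PMS2,All,70,prospective,10.7,2.8,36.5
female,MLH1,Europe,30,retrospective,0.4,0.2,0.9
female,MLH1,Europe,40,retrospective,1.3,0.6,2.9
female,MLH1,Europe,50,retrospective,4.7,2.6,8.2
female,MLH1,Europe,60,retrospective,12,8.4,18
female,MLH1,Europe,70,retrospective,22,15,32
female,MLH1,Europe,30,prospective,0,,
female,MLH1,Europe,40,prospective,8.5,5.7,12.7
female,MLH1,Europe,50,prospective,17.8,13.8,22.8
female,MLH1,Europe,60,prospective,29.9,24.7,35.9
female,MLH1,Europe,70,prospective,41.0,34.7,48.0
female,MLH1,All,25,retrospective,0.4,0.3,0.7
female,MLH1,All,30,retrospective,0.8,0.5,1.2
female,MLH1,All,40,retrospective,3.1,2.2,4.5
female,MLH1,All,50,retrospective,8.6,6.6,12
female,MLH1,All,60,retrospective,17,14,21
female,MLH1,All,70,retrospective,27,22,33
female,MLH1,All,30,prospective,0,,
female,MLH1,All,40,prospective,9.3,6.5,13.2
female,MLH1,All,50,prospective,18.2,14.5,22.9
female,MLH1,All,60,prospective,29.9,25.1,35.4
female,MLH1,All,70,prospective,41.3,35.4,47.8
female,MSH2,Europe,30,retrospective,0.4,0.2,1.0
female,MSH2,Europe,40,retrospective,1.5,0.7,3.3
female,MSH2,Europe,50,retrospective,4.7,2.6,8.9
female,MSH2,Europe,60,retrospective,10,6.7,17
female,MSH2,Europe,70,retrospective,17,11,27
female,MSH2,Europe,30,prospective,2.3,0.7,6.9
female,MSH2,Europe,40,prospective,7.2,4.1,12.4
female,MSH2,Europe,50,prospective,15.3,10.8,21.4
female,MSH2,Europe,60,prospective,23.3,17.8,30.1
female,MSH2,Europe,70,prospective,38.6,31.4,46.9
female,MSH2,All,25,retrospective,0.4,0.3,0.7
female,MSH2,All,30,retrospective,0.8,0.6,1.3
female,MSH2,All,40,retrospective,3.3,2.3,5.0
female,MSH2,All,50,retrospective,8.7,6.5,12
female,MSH2,All,60,retrospective,15,12,20
female,MSH2,All,70,retrospective,23,19,29
female,MSH2,All,30,prospective,1.8,0.6,5.4
female,MSH2,All,40,prospective,7.1,4.3,11.6
female,MSH2,All,50,prospective,15.4,11.4,20.6
female,MSH2,All,60,prospective,23.4,18.6,29.1
female,MSH2,All,70,prospective,38.7,32.5,45.6
female,MSH6,Europe,30,retrospective,0.1,0.0,0.2
female,MSH6,Europe,40,retrospective,0.2,0.1,0.7
female,MSH6,Europe,50,retrospective,0.8,0.3,2.3
female,MSH6,Europe,60,retrospective,2.5,1.3,5.5
female,MSH6,Europe,70,retrospective,5.6,2.8,11
female,MSH6,Europe,30,prospective,0,,
female,MSH6,Europe,40,prospective,0,,
female,MSH6,Europe,50,prospective,3.1,1.0,9.5
female,MSH6,Europe,60,prospective,8.2,4.4,15.3
female,MSH6,Europe,70,prospective,14.5,8.7,23.5
female,MSH6,All,25,retrospective,0.0,0.0,0.1
female,MSH6,All,30,retrospective,0.1,0.0,0.2
female,MSH6,All,40,retrospective,0.3,0.1,1.0
female,MSH6,All,50,retrospective,1.0,0.6,3.0
female,MSH6,All,60,retrospective,3.4,2.4,6.4
female,MSH6,All,70,retrospective,8.1,5.5,13
female,MSH6,All,30,prospective,0,,
female,MSH6,All,40,prospective,1.2,0.2,8.2
female,MSH6,All,50,prospective,4.0,1.5,10.4
female,MSH6,All,60,prospective,8.4,4.6,15.2
female,MSH6,All,70,prospective,16.8,10.8,25.5
female,PMS2,Europe,30,retrospective,0.1,0.1,0.1
female,PMS2,Europe,40,retrospective,0.2,0.2,0.2
female,PMS2,Europe,50,retrospective,0.9,0.8,0.9
female,PMS2,Europe,60,retrospective,2.6,2.2,3.0
female,PMS2,Europe,70,retrospective,5.3,4.2,6.6
female,PMS2,Europe,30,prospective,0,,
female,PMS2,Europe,40,prospective,0,,
female,PMS2,Europe,50,prospective,0,,
female,PMS2,Europe,60,prospective,0,,
female,PMS2,Europe,70,prospective,3.4,0.5,21.7
female,PMS2,All,25,retrospective,0.0,0.0,0.0
female,PMS2,All,30,retrospective,0.1,0.1,0.1
female,PMS2,All,40,retrospective,0.3,0.3,0.3
female,PMS2,All,50,retrospective,1.0,1.0,1.0
female,PMS2,All,60,retrospective,2.7,2.5,2.9
female,PMS2,All,70,retrospective,5.6,5.0,6.2
female,PMS2,All,30,prospective,0,,
female,PMS2,All,40,prospective,0,,
female,PMS2,All,50,prospective,0,,
female,PMS2,All,60,prospective,0,,
female,PMS2,All,70,prospective,7.9,1.9,29.3
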